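"""Multilocus genotypes, reference panels and the genotype CSV dialect.

A genotype at a locus is an unordered pair of allele labels, serialized with
the alleles sorted and joined by "/" ("C/T", "188/193"); "." marks a missing
locus. The genotype CSV has columns ``sample_id, group`` followed by one
column per locus.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

Genotype = tuple[str, str]

MISSING = "."


def make_genotype(a: str, b: str) -> Genotype:
    """Canonical (sorted) unordered allele pair."""
    return (a, b) if a <= b else (b, a)


def format_genotype(g: Optional[Genotype]) -> str:
    if g is None:
        return MISSING
    return "/".join(g)


def parse_genotype(s: str) -> Optional[Genotype]:
    s = s.strip()
    if s in ("", MISSING):
        return None
    if "/" in s:
        a, b = s.split("/", 1)
    elif len(s) == 2:
        a, b = s[0], s[1]
    else:
        raise ValueError(f"cannot parse genotype {s!r}")
    return make_genotype(a.strip(), b.strip())


@dataclass
class MultilocusGenotype:
    """A sample's genotypes at the panel loci (missing allowed)."""

    sample_id: str
    group: str  # QUROB | QUPET | Hybrid | unknown
    loci: dict[str, Optional[Genotype]] = field(default_factory=dict)

    @property
    def typed_loci(self) -> list[str]:
        return [l for l, g in self.loci.items() if g is not None]

    @property
    def n_typed(self) -> int:
        return len(self.typed_loci)

    def is_heterozygous(self, locus: str) -> bool:
        g = self.loci.get(locus)
        return g is not None and g[0] != g[1]


@dataclass
class ReferencePanel:
    """A labelled group of multilocus genotypes with derived allele counts."""

    group: str
    members: list[MultilocusGenotype] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def locus_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.members:
            for l in m.loci:
                seen.setdefault(l)
        return list(seen)

    def allele_counts(self, locus: str) -> Counter:
        counts: Counter = Counter()
        for m in self.members:
            g = m.loci.get(locus)
            if g is not None:
                counts[g[0]] += 1
                counts[g[1]] += 1
        return counts

    def n_typed(self, locus: str) -> int:
        return sum(1 for m in self.members if m.loci.get(locus) is not None)

    def modal_allele(self, locus: str) -> Optional[str]:
        counts = self.allele_counts(locus)
        if not counts:
            return None
        # deterministic tie-break by allele label
        return max(sorted(counts), key=lambda a: counts[a])

    def without(self, sample_id: str) -> "ReferencePanel":
        """Copy of the panel with one member removed (leave-one-out)."""
        return ReferencePanel(
            self.group, [m for m in self.members if m.sample_id != sample_id]
        )


def write_genotype_csv(
    samples: Iterable[MultilocusGenotype],
    path: str | Path,
    locus_ids: list[str],
    provenance: list[str] | None = None,
) -> None:
    with open(path, "w", newline="") as fh:
        for line in provenance or []:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "group", *locus_ids])
        for s in samples:
            writer.writerow(
                [s.sample_id, s.group]
                + [format_genotype(s.loci.get(l)) for l in locus_ids]
            )


def read_genotype_csv(path: str | Path) -> list[MultilocusGenotype]:
    samples = []
    with open(path, newline="") as fh:
        rows = (r for r in fh if not r.startswith("#"))
        reader = csv.reader(rows)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty genotype file") from None
        if header[:2] != ["sample_id", "group"]:
            raise ValueError(
                f"{path}: line 1: genotype CSV must start with columns "
                f"'sample_id,group', got {header[:2]}"
            )
        locus_ids = header[2:]
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: line {i}: expected {len(header)} fields, got {len(row)}"
                )
            loci = {}
            for locus, value in zip(locus_ids, row[2:]):
                try:
                    loci[locus] = parse_genotype(value)
                except ValueError as err:
                    raise ValueError(f"{path}: line {i}, column {locus}: {err}")
            samples.append(MultilocusGenotype(row[0], row[1], loci))
    return samples


def panels_from_samples(
    samples: Iterable[MultilocusGenotype],
) -> dict[str, ReferencePanel]:
    """Group samples into reference panels by their group label."""
    panels: dict[str, ReferencePanel] = {}
    for s in samples:
        panels.setdefault(s.group, ReferencePanel(s.group)).members.append(s)
    return panels
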