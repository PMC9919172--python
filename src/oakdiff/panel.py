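"""Marker panel definitions.

A *marker panel* is the set of amplified regions and the individual variants
(loci) genotyped from them. The built-in panel covers the four nuclear regions
that differentiate *Quercus robur* from *Q. petraea*: two CAPS markers
(QP_miSeq14a with MboI, QP_miSeq36 with MseI), one InDel length marker
(QP_miSeq32, 188 vs 193 bp) and one Sanger-typed two-SNP region (QP_miSeq38).
Panels are shipped and exchanged as documented YAML files (see
``data/panel.yaml`` for the schema).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

SPECIES = ("robur", "petraea")

#: canonical reference-group labels used throughout the package
GROUP_ROBUR = "QUROB"
GROUP_PETRAEA = "QUPET"
GROUP_HYBRID = "Hybrid"


@dataclass(frozen=True)
class LocusDef:
    """One typed variant within an amplified region."""

    locus_id: str
    reference: str
    position: int  # 1-based on the robur reference assembly
    vtype: str  # SNV | InDel
    ref_allele: str
    alt_allele: str
    offset: int  # 1-based within the robur amplicon, primer orientation
    robur_allele: str
    petraea_allele: str

    def __post_init__(self) -> None:
        if self.position < 1 or self.offset < 1:
            raise ValueError(f"{self.locus_id}: coordinates are 1-based")
        if self.vtype not in ("SNV", "InDel"):
            raise ValueError(f"{self.locus_id}: unsupported vtype {self.vtype!r}")

    def allele_for(self, species: str) -> str:
        return {"robur": self.robur_allele, "petraea": self.petraea_allele}[species]

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Variant-table join key (reference, position, ref allele, alt allele)."""
        return (self.reference, self.position, self.ref_allele, self.alt_allele)

    @property
    def region_number(self) -> str:
        """Short region number used in divergent-marker notes ('14', '32', ...)."""
        m = re.search(r"miSeq(\d+)", self.locus_id)
        return m.group(1) if m else self.locus_id


@dataclass(frozen=True)
class MarkerDef:
    """One amplified region: primers, genotyping method and its loci."""

    region: str
    fwd_primer: str
    rev_primer: str
    method: str  # caps | fragment_size | sanger
    enzyme: str | None
    reverse_to_reference: bool
    amplicon_len: dict[str, int]
    fragments: dict[str, list[int]]
    cut_species: str | None
    loci: tuple[LocusDef, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.fwd_primer or not self.rev_primer:
            raise ValueError(f"{self.region}: empty primer")
        if self.method not in ("caps", "fragment_size", "sanger"):
            raise ValueError(f"{self.region}: unknown method {self.method!r}")
        if self.method == "caps" and not self.enzyme:
            raise ValueError(f"{self.region}: CAPS marker requires an enzyme")
        for locus in self.loci:
            span = self.amplicon_len["robur"]
            if not 1 <= locus.offset <= span:
                raise ValueError(
                    f"{locus.locus_id}: offset {locus.offset} outside amplicon (1..{span})"
                )

    @property
    def site_locus(self) -> LocusDef | None:
        """The locus whose allele creates/destroys the restriction site (CAPS only)."""
        if self.method != "caps":
            return None
        # by construction the first locus of a CAPS region carries the site
        return self.loci[0]

    def locus(self, locus_id: str) -> LocusDef:
        for loc in self.loci:
            if loc.locus_id == locus_id:
                return loc
        raise KeyError(locus_id)


class Panel:
    """An ordered collection of :class:`MarkerDef`."""

    def __init__(self, markers: list[MarkerDef]):
        self.markers = list(markers)
        self._by_region = {m.region: m for m in self.markers}
        if len(self._by_region) != len(self.markers):
            raise ValueError("duplicate region names in panel")

    def __iter__(self):
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def region(self, name: str) -> MarkerDef:
        return self._by_region[name]

    @property
    def locus_ids(self) -> list[str]:
        return [loc.locus_id for m in self.markers for loc in m.loci]

    @property
    def loci(self) -> list[LocusDef]:
        return [loc for m in self.markers for loc in m.loci]

    def find_locus(self, locus_id: str) -> tuple[MarkerDef, LocusDef]:
        for m in self.markers:
            for loc in m.loci:
                if loc.locus_id == locus_id:
                    return m, loc
        raise KeyError(locus_id)


def _marker_from_dict(rec: dict) -> MarkerDef:
    loci = tuple(
        LocusDef(
            locus_id=l["id"],
            reference=l["reference"],
            position=int(l["position"]),
            vtype=l["vtype"],
            ref_allele=str(l["ref_allele"]),
            alt_allele=str(l["alt_allele"]),
            offset=int(l["offset"]),
            robur_allele=str(l["robur_allele"]),
            petraea_allele=str(l["petraea_allele"]),
        )
        for l in rec["loci"]
    )
    return MarkerDef(
        region=rec["region"],
        fwd_primer=rec["fwd_primer"],
        rev_primer=rec["rev_primer"],
        method=rec["method"],
        enzyme=rec.get("enzyme"),
        reverse_to_reference=bool(rec.get("reverse_to_reference", False)),
        amplicon_len={k: int(v) for k, v in rec["amplicon_len"].items()},
        fragments={k: [int(x) for x in v] for k, v in rec["fragments"].items()},
        cut_species=rec.get("cut_species"),
        loci=loci,
    )


def load_panel(path: str | Path | None = None) -> Panel:
    """Load a marker panel from YAML; the built-in six-locus panel by default."""
    if path is None:
        text = resources.files("oakdiff.data").joinpath("panel.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "markers" not in doc:
        raise ValueError("panel file must contain a top-level 'markers' list")
    return Panel([_marker_from_dict(rec) for rec in doc["markers"]])


def write_panel(panel: Panel, path: str | Path) -> None:
    doc = {
        "markers": [
            {
                "region": m.region,
                "fwd_primer": m.fwd_primer,
                "rev_primer": m.rev_primer,
                "method": m.method,
                "enzyme": m.enzyme,
                "reverse_to_reference": m.reverse_to_reference,
                "amplicon_len": m.amplicon_len,
                "fragments": m.fragments,
                "cut_species": m.cut_species,
                "loci": [
                    {
                        "id": l.locus_id,
                        "reference": l.reference,
                        "position": l.position,
                        "vtype": l.vtype,
                        "ref_allele": l.ref_allele,
                        "alt_allele": l.alt_allele,
                        "offset": l.offset,
                        "robur_allele": l.robur_allele,
                        "petraea_allele": l.petraea_allele,
                    }
                    for l in m.loci
                ],
            }
            for m in panel
        ]
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@lru_cache(maxsize=1)
def default_panel() -> Panel:
    return load_panel(None)
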