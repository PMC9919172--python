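"""Synthetic-data generator for the oak marker pipeline.

Every downstream stage is testable without the original sequencing data:
this module fabricates (i) marker-region template sequences whose in-silico
PCR and digestion products reproduce the published amplicon and fragment
lengths, (ii) pool variant tables with planted truth that exercise each
stage of the fixed-difference cascade, and (iii) reference genotype panels
whose genotype-class frequencies reconstruct the published validation
counts (39 *Q. robur* / 45 *Q. petraea* / 20 hybrids; 77/77 at the InDel
marker).

Published fragment sizes, not internal amplicon layouts, are the contract:
the generator places variant and enzyme sites at fixed offsets chosen to
satisfy those sizes and records the layout in a sidecar manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .assign import posterior_mean_freqs
from .genotypes import Genotype, MultilocusGenotype, ReferencePanel, make_genotype
from .insilico import ENZYMES, digest, revcomp
from .panel import GROUP_HYBRID, GROUP_PETRAEA, GROUP_ROBUR, MarkerDef, Panel, default_panel
from .pooldiff import PoolVariant, VariantKey

BASES = "ACGT"

#: genotype-class percentages observed in the validation reference panels
#: (N = 39 Q. robur / 45 Q. petraea; 77/77 at the InDel marker)
REFERENCE_GENOTYPE_FREQS: dict[str, dict[str, dict[str, float]]] = {
    GROUP_ROBUR: {
        "QP_miSeq14a_SNP1": {"T/T": 100},
        "QP_miSeq14a_SNP2": {"C/C": 100},
        "QP_miSeq32_InDel": {"188/188": 96, "188/193": 4},
        "QP_miSeq36_SNP": {"T/T": 85, "C/T": 13, "C/C": 2},
        "QP_miSeq38_SNP1": {"G/G": 92, "A/G": 8},
        "QP_miSeq38_SNP2": {"A/A": 92, "A/C": 8},
    },
    GROUP_PETRAEA: {
        "QP_miSeq14a_SNP1": {"C/C": 84, "C/T": 16},
        "QP_miSeq14a_SNP2": {"T/T": 84, "C/T": 16},
        "QP_miSeq32_InDel": {"193/193": 64, "188/188": 18, "188/193": 18},
        "QP_miSeq36_SNP": {"C/C": 81, "C/T": 15, "T/T": 4},
        "QP_miSeq38_SNP1": {"A/A": 93, "A/G": 7},
        "QP_miSeq38_SNP2": {"C/C": 93, "A/C": 7},
    },
}


# ---------------------------------------------------------------------------
# marker templates


@dataclass(frozen=True)
class MarkerTemplate:
    """A synthetic genomic template carrying one allele of a marker region."""

    marker_id: str
    species_allele: str  # robur | petraea | petraea-caucasus
    sequence: str
    primer_span_fwd: tuple[int, int]  # 1-based inclusive, template coordinates
    primer_span_rev: tuple[int, int]
    variant_offsets: dict[str, int]  # locus id -> 1-based position in the template
    strand: str = "+"  # '-' when the template is stored in reference orientation

    @property
    def fasta_id(self) -> str:
        return f"{self.marker_id}|{self.species_allele}"


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _fixed_amplicon_bases(marker: MarkerDef) -> dict[int, str]:
    """Invariant bases around enzyme sites (1-based amplicon offsets)."""
    fixed: dict[int, str] = {}
    if marker.region == "QP_miSeq14a":
        # MboI site GATC at offsets 81-84 in the petraea allele (cut ^GATC ->
        # fragments 80 + 107); offset 84 is SNP1. Offset 85 is fixed G so the
        # minus-strand codon over 84-86 reads GCA (Ala) in robur and ACG (Thr)
        # with the petraea alleles, matching the predicted protein exchange.
        fixed.update({81: "G", 82: "A", 83: "T", 85: "G"})
    elif marker.region == "QP_miSeq36":
        # MseI site TTAA at offsets 86-89 in the robur allele (cut T^TAA ->
        # fragments 86 + 83); offset 86 is the diagnostic SNP
        fixed.update({87: "T", 88: "A", 89: "A"})
    return fixed


def _build_robur_amplicon(rng: np.random.Generator, marker: MarkerDef) -> str:
    length = marker.amplicon_len["robur"]
    fwd = marker.fwd_primer
    rev_rc = revcomp(marker.rev_primer)
    interior_len = length - len(fwd) - len(rev_rc)
    if interior_len < 0:
        raise ValueError(f"{marker.region}: primers longer than the amplicon")
    seq = list(fwd + _rand_seq(rng, interior_len) + rev_rc)
    for off, base in _fixed_amplicon_bases(marker).items():
        seq[off - 1] = base
    for locus in marker.loci:
        if locus.vtype == "SNV":
            seq[locus.offset - 1] = locus.robur_allele
    return "".join(seq)


def _petraea_amplicon(marker: MarkerDef, robur_amplicon: str) -> str:
    """Derive the petraea-allele amplicon by applying the marker's variants."""
    from .insilico import apply_variant

    seq = robur_amplicon
    # apply from the highest offset down so insertions do not shift SNPs
    for locus in sorted(marker.loci, key=lambda l: -l.offset):
        if locus.vtype == "InDel":
            seq = apply_variant(seq, locus.offset, "-", locus.alt_allele)
        else:
            seq = apply_variant(
                seq, locus.offset, locus.robur_allele, locus.petraea_allele
            )
    return seq


def _amplicon_constraints_ok(marker: MarkerDef, rob_amp: str, pet_amp: str) -> bool:
    for amp in (rob_amp, pet_amp):
        if amp.count(marker.fwd_primer) != 1:
            return False
        if amp.count(revcomp(marker.rev_primer)) != 1:
            return False
        # primers must not match the opposite strand either
        rc = revcomp(amp)
        if rc.count(marker.fwd_primer) or rc.count(revcomp(marker.rev_primer)):
            return False
    if marker.method == "caps":
        enzyme = ENZYMES[marker.enzyme]
        cut_amp = rob_amp if marker.cut_species == "robur" else pet_amp
        uncut_amp = pet_amp if marker.cut_species == "robur" else rob_amp
        if digest(cut_amp, enzyme) != marker.fragments[marker.cut_species]:
            return False
        if len(digest(uncut_amp, enzyme)) != 1:
            return False
    return True


def _template_constraints_ok(marker: MarkerDef, template: str) -> bool:
    rc = revcomp(template)
    fwd, rev_rc = marker.fwd_primer, revcomp(marker.rev_primer)
    n_plus = template.count(fwd)
    n_minus = rc.count(fwd)
    return (
        n_plus + n_minus == 1
        and template.count(rev_rc) + rc.count(rev_rc) == 1
    )


def make_marker_templates(
    seed: int,
    panel: Optional[Panel] = None,
    flank: int = 30,
    max_tries: int = 200,
) -> list[MarkerTemplate]:
    """Generate template sequences for every region and allele (seeded).

    Each region yields a robur and a petraea template sharing flanks and
    filler (they represent the same genomic region); the InDel region
    additionally yields the Caucasus-origin petraea allele, which carries
    the short (robur-length) amplicon. Filler sequence is redrawn until no
    spurious primer or enzyme site occurs.
    """
    panel = panel or default_panel()
    rng = np.random.default_rng(seed)
    templates: list[MarkerTemplate] = []
    for marker in panel:
        for _ in range(max_tries):
            rob_amp = _build_robur_amplicon(rng, marker)
            pet_amp = _petraea_amplicon(marker, rob_amp)
            if not _amplicon_constraints_ok(marker, rob_amp, pet_amp):
                continue
            left = _rand_seq(rng, flank)
            right = _rand_seq(rng, flank)
            rob_tpl = left + rob_amp + right
            pet_tpl = left + pet_amp + right
            if all(
                _template_constraints_ok(marker, t) for t in (rob_tpl, pet_tpl)
            ):
                break
        else:
            raise RuntimeError(
                f"{marker.region}: could not satisfy template constraints "
                f"in {max_tries} draws"
            )
        for allele, tpl, amp in (
            ("robur", rob_tpl, rob_amp),
            ("petraea", pet_tpl, pet_amp),
        ):
            shift = 0 if allele == "robur" else _indel_shift(marker)
            offsets = {}
            for locus in marker.loci:
                off = locus.offset
                if allele == "petraea" and locus.vtype == "SNV":
                    off += shift if _indel_before(marker, locus) else 0
                offsets[locus.locus_id] = flank + off
            fwd_span = (flank + 1, flank + len(marker.fwd_primer))
            rev_span = (
                flank + len(amp) - len(marker.rev_primer) + 1,
                flank + len(amp),
            )
            strand = "+"
            if marker.reverse_to_reference:
                # store in reference orientation: primers then sit on the minus strand
                n = len(tpl)
                tpl = revcomp(tpl)
                offsets = {k: n - v + 1 for k, v in offsets.items()}
                fwd_span = (n - fwd_span[1] + 1, n - fwd_span[0] + 1)
                rev_span = (n - rev_span[1] + 1, n - rev_span[0] + 1)
                strand = "-"
            templates.append(
                MarkerTemplate(
                    marker_id=marker.region,
                    species_allele=allele,
                    sequence=tpl,
                    primer_span_fwd=fwd_span,
                    primer_span_rev=rev_span,
                    variant_offsets=offsets,
                    strand=strand,
                )
            )
        if any(l.vtype == "InDel" for l in marker.loci):
            rob_template = templates[-2]
            templates.append(
                replace(rob_template, species_allele="petraea-caucasus")
            )
    return templates


def _indel_shift(marker: MarkerDef) -> int:
    return sum(len(l.alt_allele) for l in marker.loci if l.vtype == "InDel")


def _indel_before(marker: MarkerDef, locus) -> bool:
    return any(
        l.vtype == "InDel" and l.offset <= locus.offset for l in marker.loci
    )


def templates_manifest(templates: Sequence[MarkerTemplate]) -> dict:
    """Sidecar manifest documenting the generated amplicon layouts."""
    return {
        "templates": [
            {
                "id": t.fasta_id,
                "marker": t.marker_id,
                "allele": t.species_allele,
                "length": len(t.sequence),
                "strand": t.strand,
                "primer_span_fwd": list(t.primer_span_fwd),
                "primer_span_rev": list(t.primer_span_rev),
                "variant_offsets": t.variant_offsets,
            }
            for t in templates
        ]
    }


def build_haplotype(
    marker: MarkerDef, robur_amplicon: str, alleles: dict[str, str]
) -> str:
    """Construct one haplotype amplicon carrying the given marker-orientation
    alleles (locus id -> allele label)."""
    from .insilico import apply_variant

    seq = robur_amplicon
    for locus in sorted(marker.loci, key=lambda l: -l.offset):
        allele = alleles.get(locus.locus_id, locus.robur_allele)
        if locus.vtype == "InDel":
            if allele == locus.petraea_allele:
                seq = apply_variant(seq, locus.offset, "-", locus.alt_allele)
        elif allele != locus.robur_allele:
            seq = apply_variant(seq, locus.offset, locus.robur_allele, allele)
    return seq


# ---------------------------------------------------------------------------
# pool variant tables with planted truth


@dataclass
class TruthSet:
    """Bookkeeping for planted variants: which must survive the cascade and
    which must be removed, tagged with the stage that removes them."""

    planted_diagnostic: set[VariantKey] = field(default_factory=set)
    planted_background: dict[VariantKey, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.planted_diagnostic & set(self.planted_background)
        if overlap:
            raise ValueError(f"diagnostic and background sets overlap: {overlap}")


_BACKGROUND_STAGES = ("pet_alt_freq", "pet_cov", "rob_nocov", "rob_ref_freq", "rob_cov")

_CONTIGS = [f"Chr{i}" for i in range(1, 13)] + ["scaffold492", "scaffold817"]


def _draw_cov(rng: np.random.Generator, mean: float, minimum: int) -> int:
    return max(int(rng.poisson(mean)), minimum)


def make_pool_variant_tables(
    seed: int,
    n_diagnostic: int,
    n_background: int,
    cov_pet_mean: float = 29.0,
    cov_rob_mean: float = 19.0,
    panel: Optional[Panel] = None,
) -> tuple[list[PoolVariant], list[PoolVariant], dict[tuple[str, int], int], TruthSet]:
    """Simulate the two pools' variant tables and the robur coverage track.

    Diagnostic variants are fixed differences (petraea alternative allele at
    100% with coverage >= 13; robur reference allele at 100% with coverage
    >= 5). Background variants each violate exactly one cascade stage, with
    the violated stage recorded in the returned :class:`TruthSet`. Coverage
    is Poisson around the nominal pool depths (29X petraea, 19X robur).
    When a *panel* is given, its diagnostic variants fill the first
    ``min(n_diagnostic, 6)`` slots at their real coordinates.
    """
    if n_diagnostic < 0 or n_background < 0:
        raise ValueError("variant counts must be non-negative")
    if n_diagnostic + n_background < 1:
        raise ValueError("at least one variant must be planted")
    rng = np.random.default_rng(seed)
    pet_rows: list[PoolVariant] = []
    rob_rows: list[PoolVariant] = []
    coverage: dict[tuple[str, int], int] = {}
    truth = TruthSet()
    used_positions: set[tuple[str, int]] = set()

    def new_key(ref=None, pos=None, ref_allele=None, alt_allele=None) -> VariantKey:
        while ref is None or (ref, pos) in used_positions:
            ref = _CONTIGS[rng.integers(0, len(_CONTIGS))]
            pos = int(rng.integers(1, 5_000_000))
        used_positions.add((ref, pos))
        if ref_allele is None:
            kind = rng.random()
            if kind < 0.8:  # SNV
                ref_allele = BASES[rng.integers(0, 4)]
                alt_allele = BASES[(BASES.index(ref_allele) + rng.integers(1, 4)) % 4]
            elif kind < 0.9:  # MNV
                ref_allele = _rand_seq(rng, 2)
                alt_allele = "".join(
                    BASES[(BASES.index(b) + 1) % 4] for b in ref_allele
                )
            else:  # insertion
                ref_allele = "-"
                alt_allele = _rand_seq(rng, int(rng.integers(1, 6)))
        return (ref, pos, ref_allele, alt_allele)

    panel_keys: list[VariantKey] = []
    if panel is not None:
        panel_keys = [loc.key for loc in panel.loci]
        for ref, pos, *_ in panel_keys:
            used_positions.add((ref, pos))

    def vtype_of(ref_allele: str, alt_allele: str) -> str:
        if ref_allele == "-" or alt_allele == "-":
            return "InDel"
        return "SNV" if len(ref_allele) == 1 else "MNV"

    for i in range(n_diagnostic):
        if i < len(panel_keys):
            key = panel_keys[i]
        else:
            key = new_key()
        ref, pos, ra, aa = key
        cov = _draw_cov(rng, cov_pet_mean, 13)
        pet_rows.append(
            PoolVariant(ref, pos, vtype_of(ra, aa), ra, aa, cov, cov, 100.0)
        )
        coverage[(ref, pos)] = _draw_cov(rng, cov_rob_mean, 5)
        truth.planted_diagnostic.add(key)

    for i in range(n_background):
        stage = _BACKGROUND_STAGES[i % len(_BACKGROUND_STAGES)]
        key = new_key()
        ref, pos, ra, aa = key
        vt = vtype_of(ra, aa)
        if stage == "pet_alt_freq":
            cov = _draw_cov(rng, cov_pet_mean, 13)
            count = int(rng.integers(cov // 2, cov))  # < 100% by at least one read
            pet_rows.append(
                PoolVariant(ref, pos, vt, ra, aa, count, cov, 100.0 * count / cov)
            )
            coverage[(ref, pos)] = _draw_cov(rng, cov_rob_mean, 5)
        elif stage == "pet_cov":
            cov = int(rng.integers(1, 13))
            pet_rows.append(PoolVariant(ref, pos, vt, ra, aa, cov, cov, 100.0))
            coverage[(ref, pos)] = _draw_cov(rng, cov_rob_mean, 5)
        elif stage == "rob_nocov":
            cov = _draw_cov(rng, cov_pet_mean, 13)
            pet_rows.append(PoolVariant(ref, pos, vt, ra, aa, cov, cov, 100.0))
            # position deliberately absent from the robur coverage track
        elif stage == "rob_ref_freq":
            cov = _draw_cov(rng, cov_pet_mean, 13)
            pet_rows.append(PoolVariant(ref, pos, vt, ra, aa, cov, cov, 100.0))
            rob_cov = _draw_cov(rng, cov_rob_mean, 5)
            rob_alt = int(rng.integers(1, rob_cov))
            rob_rows.append(
                PoolVariant(
                    ref, pos, vt, ra, aa, rob_alt, rob_cov, 100.0 * rob_alt / rob_cov
                )
            )
            coverage[(ref, pos)] = rob_cov
        elif stage == "rob_cov":
            cov = _draw_cov(rng, cov_pet_mean, 13)
            pet_rows.append(PoolVariant(ref, pos, vt, ra, aa, cov, cov, 100.0))
            coverage[(ref, pos)] = int(rng.integers(1, 5))
        truth.planted_background[key] = stage

    return pet_rows, rob_rows, coverage, truth


# ---------------------------------------------------------------------------
# reference panels from published genotype-class percentages


@dataclass
class PanelConfig:
    """Configuration of the reconstructed reference panels."""

    n_robur: int = 39
    n_petraea: int = 45
    n_hybrid: int = 20
    n_indel_extra_robur: int = 38  # InDel-only individuals -> 77 typed
    n_indel_extra_petraea: int = 32
    genotype_freqs: dict[str, dict[str, dict[str, float]]] | None = None
    hybrid_generation: str = "F1"
    seed: int = 1

    def __post_init__(self) -> None:
        for count in (self.n_robur, self.n_petraea, self.n_hybrid):
            if count <= 0:
                raise ValueError("panel sizes must be positive")
        if self.n_indel_extra_robur < 0 or self.n_indel_extra_petraea < 0:
            raise ValueError("InDel-only counts must be non-negative")
        freqs = self.genotype_freqs or REFERENCE_GENOTYPE_FREQS
        for group, loci in freqs.items():
            for locus, classes in loci.items():
                total = sum(classes.values())
                # integer-printed class percentages of one locus sum to 100;
                # only sub-point rounding slack is accepted
                if abs(total - 100.0) > 0.5:
                    raise ValueError(
                        f"{group}/{locus}: genotype-class percentages sum to "
                        f"{total}, not 100"
                    )

    @property
    def freqs(self) -> dict[str, dict[str, dict[str, float]]]:
        return self.genotype_freqs or REFERENCE_GENOTYPE_FREQS


def split_percentages(freqs: dict[str, float], n: int) -> dict[str, int]:
    """Integer genotype counts whose rounded percentages match *freqs*.

    Chooses the split minimizing the maximum deviation of the rounded
    percentage from the printed value; deviations above one point are
    rejected. Ambiguities resolve toward the first-listed (homozygote)
    class.
    """
    classes = list(freqs)
    base = [int(np.floor(freqs[c] * n / 100.0)) for c in classes]

    def rounded(counts: list[int]) -> list[int]:
        return [round(100.0 * c / n) for c in counts]

    best: tuple[float, tuple[int, ...]] | None = None
    spans = [range(max(0, b - 2), min(n, b + 3) + 1) for b in base[:-1]]

    def search(idx: int, acc: list[int], remaining: int) -> None:
        nonlocal best
        if idx == len(classes) - 1:
            counts = acc + [remaining]
            if remaining < 0:
                return
            devs = [
                abs(r - freqs[c]) for r, c in zip(rounded(counts), classes)
            ]
            key = (max(devs), sum(devs), -counts[0])
            if best is None or key < best[0]:
                best = (key, tuple(counts))
            return
        for c in spans[idx]:
            if c <= remaining:
                search(idx + 1, acc + [c], remaining - c)

    search(0, [], n)
    if best is None or best[0][0] > 1.0:
        raise ValueError(
            f"percentages {freqs} cannot be realized as {n} integer counts "
            "within +/-1 point"
        )
    return dict(zip(classes, best[1]))


def _parse_class(label: str) -> Genotype:
    a, b = label.split("/")
    return make_genotype(a, b)


def make_reference_panels(
    cfg: PanelConfig | None = None, panel: Optional[Panel] = None
) -> dict[str, ReferencePanel]:
    """Reconstruct the QUROB / QUPET reference panels and simulate hybrids.

    Genotype classes are assigned to individuals independently per locus
    (the published table reports only marginal class frequencies), with a
    seeded shuffle. InDel-only individuals extend the InDel marker to its
    larger validation set.
    """
    cfg = cfg or PanelConfig()
    panel = panel or default_panel()
    rng = np.random.default_rng(cfg.seed)
    locus_ids = panel.locus_ids
    indel_locus = next(
        (l.locus_id for l in panel.loci if l.vtype == "InDel"), None
    )

    panels: dict[str, ReferencePanel] = {}
    specs = [
        (GROUP_ROBUR, cfg.n_robur, cfg.n_indel_extra_robur),
        (GROUP_PETRAEA, cfg.n_petraea, cfg.n_indel_extra_petraea),
    ]
    for group, n_core, n_extra in specs:
        freqs = cfg.freqs[group]
        prefix = "QUROB" if group == GROUP_ROBUR else "QUPET"
        members = [
            MultilocusGenotype(f"{prefix}_{i + 1:03d}", group, {})
            for i in range(n_core)
        ]
        extras = [
            MultilocusGenotype(f"{prefix}_IND_{i + 1:03d}", group, {})
            for i in range(n_extra)
        ]
        for locus in locus_ids:
            if locus not in freqs:
                continue
            targets = members + extras if locus == indel_locus else members
            counts = split_percentages(freqs[locus], len(targets))
            pool = [
                _parse_class(label)
                for label, c in counts.items()
                for _ in range(c)
            ]
            order = rng.permutation(len(targets))
            for slot, genotype in zip(order, pool):
                targets[slot].loci[locus] = genotype
        for extra in extras:
            for locus in locus_ids:
                extra.loci.setdefault(locus, None)
        panels[group] = ReferencePanel(group, members + extras)

    hybrid_members = [
        simulate_hybrid(
            rng,
            cfg.hybrid_generation,
            (panels[GROUP_ROBUR], panels[GROUP_PETRAEA]),
            sample_id=f"HYB_{i + 1:03d}",
            loci=locus_ids,
        )
        for i in range(cfg.n_hybrid)
    ]
    panels[GROUP_HYBRID] = ReferencePanel(GROUP_HYBRID, hybrid_members)
    return panels


def _draw_allele(
    rng: np.random.Generator, panel: ReferencePanel, locus: str, alleles: tuple[str, ...]
) -> str:
    freqs = posterior_mean_freqs(panel.allele_counts(locus), alleles)
    return alleles[rng.choice(len(alleles), p=freqs)]


def simulate_hybrid(
    rng: np.random.Generator | int,
    generation: str,
    parent_panels: tuple[ReferencePanel, ReferencePanel],
    sample_id: str = "HYB_001",
    loci: Optional[Sequence[str]] = None,
) -> MultilocusGenotype:
    """Simulate one hybrid multilocus genotype (seeded).

    F1: at every locus one allele is drawn from each parental panel's
    posterior-mean allele frequencies. Backcross: one allele from the first
    (recurrent) parent, the other from an F1 allele distribution (an even
    mixture of the two parental frequency distributions). Draws are
    independent across loci.
    """
    if generation not in ("F1", "backcross"):
        raise ValueError(f"unknown hybrid generation {generation!r}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    p1, p2 = parent_panels
    if loci is None:
        loci = [l for l in p1.locus_ids if l in set(p2.locus_ids)]
    genotype: dict[str, Optional[Genotype]] = {}
    for locus in loci:
        c1, c2 = p1.allele_counts(locus), p2.allele_counts(locus)
        if not c1 or not c2:
            raise ValueError(f"parental panels must be non-empty at {locus}")
        alleles = tuple(sorted(set(c1) | set(c2)))
        a = _draw_allele(rng, p1, locus, alleles)
        if generation == "F1":
            b = _draw_allele(rng, p2, locus, alleles)
        else:  # backcross: second allele from a random F1 gamete
            donor = p1 if rng.random() < 0.5 else p2
            b = _draw_allele(rng, donor, locus, alleles)
        genotype[locus] = make_genotype(a, b)
    return MultilocusGenotype(sample_id, GROUP_HYBRID, genotype)


def simulate_pure(
    rng: np.random.Generator,
    panel: ReferencePanel,
    sample_id: str,
    loci: Sequence[str],
    group: str = "unknown",
) -> MultilocusGenotype:
    """Draw a pure-species genotype from a panel's posterior-mean frequencies."""
    genotype: dict[str, Optional[Genotype]] = {}
    for locus in loci:
        counts = panel.allele_counts(locus)
        alleles = tuple(sorted(counts))
        a = _draw_allele(rng, panel, locus, alleles)
        b = _draw_allele(rng, panel, locus, alleles)
        genotype[locus] = make_genotype(a, b)
    return MultilocusGenotype(sample_id, group, genotype)


# ---------------------------------------------------------------------------
# coding-sequence fixture for the amino-acid exchange


@dataclass(frozen=True)
class CdsFixture:
    """A synthetic CDS around the coding marker's two SNPs.

    The CDS sits on the minus strand of the genomic fragment; codon 125 is
    GCA (alanine) for the robur allele and becomes ACG (threonine) with the
    petraea alleles, matching the diagnostic SNP pair two bases apart.
    """

    genomic_fragment: str  # plus strand; CDS is its reverse complement
    cds_sequence: str  # robur allele, CDS orientation
    cds_span: tuple[int, int]
    strand: str
    variants_genomic: list[tuple[int, str, str]]
    gene: str = "detoxification 56-like"


_STOPS = {"TAA", "TAG", "TGA"}


def make_cds_fixture(seed: int = 1, n_codons: int = 125) -> CdsFixture:
    """Build a synthetic CDS whose codon 125 carries the Ala/Thr exchange."""
    if n_codons < 125:
        raise ValueError("fixture needs at least 125 codons")
    rng = np.random.default_rng(seed)
    codons = []
    while len(codons) < n_codons:
        codon = _rand_seq(rng, 3)
        if codon not in _STOPS:
            codons.append(codon)
    codons[124] = "GCA"  # alanine at protein position 125
    cds = "".join(codons)
    fragment = revcomp(cds)
    length = len(cds)
    # codon 125 occupies CDS positions 373-375 -> fragment positions
    # (length-374 .. length-372); the two substitutions sit two bases apart
    g1 = length - 375 + 1  # CDS position 375 on the plus strand
    g2 = length - 373 + 1
    variants = [(g1, "T", "C"), (g2, "C", "T")]
    for pos, ref, _ in variants:
        assert fragment[pos - 1] == ref
    return CdsFixture(
        genomic_fragment=fragment,
        cds_sequence=cds,
        cds_span=(1, length),
        strand="-",
        variants_genomic=variants,
    )
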