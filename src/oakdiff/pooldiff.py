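"""Fixed-difference discovery from two Pool-seq variant tables.

The *Q. petraea* pool's variants (called against the *Q. robur* reference)
are merged with coverage evidence from a parallel *Q. robur* pool mapping,
then reduced to fixed interspecific differences by a four-stage cascade:

1. alternative-allele frequency of 100% in the petraea pool,
2. petraea coverage at the variant position >= 13,
3. removal of variants with no robur mapping coverage at all,
4. robur reference-allele frequency of 100% with robur coverage >= 5.

Frequencies are compared exactly after rounding to one decimal, the precision
of the variant-caller tables: "100%" is the definition of a fixed difference,
not a tolerance band. Per-stage counts are reported so that real-data runs
can be compared, stage by stage, with the narrative count chain of the
original discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

VTYPES = ("SNV", "MNV", "InDel")

#: cascade stage tags, in application order
STAGES = ("pet_alt_freq", "pet_cov", "rob_nocov", "rob_ref_freq", "rob_cov")

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class PoolVariant:
    """One putative variant from a pooled mapping.

    ``ref_allele``/``alt_allele`` follow the dash convention: "-" as the
    reference allele marks an insertion, "-" as the alternative a deletion.
    ``alt_freq`` is a percentage (100 * alt_count / coverage).
    """

    reference: str
    position: int
    vtype: str
    ref_allele: str
    alt_allele: str
    alt_count: int
    coverage: int
    alt_freq: float
    anchor_base: str = field(default="N", compare=False)  # for VCF round-trips

    def __post_init__(self) -> None:
        if self.vtype not in VTYPES:
            raise ValueError(f"unknown variant type {self.vtype!r}")
        if self.position < 1:
            raise ValueError("positions are 1-based")
        if not 0 <= self.alt_freq <= 100:
            raise ValueError(f"alt_freq {self.alt_freq} outside [0, 100]")
        if self.alt_count > self.coverage:
            raise ValueError("alt_count exceeds coverage")
        if self.vtype == "MNV" and (
            len(self.ref_allele) > 2 or len(self.alt_allele) > 2
        ):
            raise ValueError("MNV alleles are limited to length <= 2")

    @property
    def key(self) -> VariantKey:
        return (self.reference, self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class MergedVariant:
    """A petraea-pool variant joined with robur-pool evidence.

    ``rob_ref_freq`` is the percentage of robur reads supporting the
    reference allele; it is None (undefined) when ``rob_coverage`` is 0.
    """

    pet: PoolVariant
    rob_coverage: int
    rob_ref_freq: Optional[float]

    def __post_init__(self) -> None:
        if self.rob_coverage < 0:
            raise ValueError("rob_coverage must be >= 0")
        if (self.rob_ref_freq is None) != (self.rob_coverage == 0):
            raise ValueError("rob_ref_freq is defined iff rob_coverage > 0")

    @property
    def key(self) -> VariantKey:
        return self.pet.key


@dataclass(frozen=True)
class FilterThresholds:
    min_cov_petraea: int = 13
    min_cov_robur: int = 5
    required_alt_freq: float = 100.0
    required_ref_freq: float = 100.0

    def __post_init__(self) -> None:
        if min(self.min_cov_petraea, self.min_cov_robur) < 0:
            raise ValueError("coverage thresholds must be non-negative")
        for f in (self.required_alt_freq, self.required_ref_freq):
            if not 0 <= f <= 100:
                raise ValueError("required frequencies must lie in [0, 100]")


@dataclass(frozen=True)
class PoolMeta:
    """Provenance of a pooled mapping; never used in computation."""

    pool: str
    n_individuals: int
    nominal_coverage: float
    length_fraction: float = 0.94
    similarity_fraction: float = 0.98


@dataclass
class CascadeReport:
    """Record counts after each cascade stage (monotonically non-increasing)."""

    n_input: int = 0
    n_after_alt_freq: int = 0
    n_after_pet_cov: int = 0
    n_removed_rob_nocov: int = 0
    n_after_rob_nocov: int = 0
    n_final: int = 0

    def to_dict(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "alt_freq_100_pass": self.n_after_alt_freq,
            "petraea_coverage_pass": self.n_after_pet_cov,
            "robur_no_coverage_removed": self.n_removed_rob_nocov,
            "robur_coverage_known": self.n_after_rob_nocov,
            "robur_ref_freq_and_coverage_pass": self.n_final,
        }

    @property
    def stage_counts(self) -> list[int]:
        return [
            self.n_input,
            self.n_after_alt_freq,
            self.n_after_pet_cov,
            self.n_after_rob_nocov,
            self.n_final,
        ]


def _round_freq(freq: float) -> float:
    return round(freq, 1)


def classify_variant(mv: MergedVariant, t: FilterThresholds) -> Optional[str]:
    """Return the stage tag at which *mv* is removed, or None if it survives."""
    if _round_freq(mv.pet.alt_freq) != _round_freq(t.required_alt_freq):
        return "pet_alt_freq"
    if mv.pet.coverage < t.min_cov_petraea:
        return "pet_cov"
    if mv.rob_coverage == 0:
        return "rob_nocov"
    if _round_freq(mv.rob_ref_freq) != _round_freq(t.required_ref_freq):
        return "rob_ref_freq"
    if mv.rob_coverage < t.min_cov_robur:
        return "rob_cov"
    return None


def merge_pools(
    pet: Iterable[PoolVariant],
    rob: Iterable[PoolVariant],
    rob_cov: Mapping[tuple[str, int], int],
) -> list[MergedVariant]:
    """Join petraea-pool variants with robur-pool evidence.

    The join key is (reference, position, ref allele, alt allele). Where the
    robur pool called any variant at the position, the robur reference-allele
    frequency is 100 minus the summed alternative frequencies there;
    otherwise a position with depth in the coverage track counts as 100%
    reference, and absent positions as no coverage.
    """
    pet = list(pet)
    rob = list(rob)
    for pool_name, pool in (("petraea", pet), ("robur", rob)):
        seen: set[VariantKey] = set()
        for v in pool:
            if v.key in seen:
                raise ValueError(f"duplicate variant key in {pool_name} pool: {v.key}")
            seen.add(v.key)

    rob_by_pos: dict[tuple[str, int], list[PoolVariant]] = {}
    for v in rob:
        rob_by_pos.setdefault((v.reference, v.position), []).append(v)

    merged = []
    for v in pet:
        pos_key = (v.reference, v.position)
        if pos_key in rob_by_pos:
            rows = rob_by_pos[pos_key]
            coverage = max(r.coverage for r in rows)
            ref_freq = max(0.0, 100.0 - sum(r.alt_freq for r in rows))
            merged.append(MergedVariant(v, coverage, ref_freq))
        else:
            depth = int(rob_cov.get(pos_key, 0))
            if depth > 0:
                merged.append(MergedVariant(v, depth, 100.0))
            else:
                merged.append(MergedVariant(v, 0, None))
    return merged


def apply_filter_cascade(
    merged: Iterable[MergedVariant], t: FilterThresholds
) -> tuple[list[MergedVariant], CascadeReport]:
    """Apply the four-stage fixed-difference cascade; order-independent.

    Returns the surviving variants (sorted by key) and a
    :class:`CascadeReport` with counts after every stage.
    """
    merged = list(merged)
    report = CascadeReport(n_input=len(merged))

    stage1 = [
        m
        for m in merged
        if _round_freq(m.pet.alt_freq) == _round_freq(t.required_alt_freq)
    ]
    report.n_after_alt_freq = len(stage1)

    stage2 = [m for m in stage1 if m.pet.coverage >= t.min_cov_petraea]
    report.n_after_pet_cov = len(stage2)

    stage3 = [m for m in stage2 if m.rob_coverage > 0]
    report.n_removed_rob_nocov = len(stage2) - len(stage3)
    report.n_after_rob_nocov = len(stage3)

    survivors = [
        m
        for m in stage3
        if _round_freq(m.rob_ref_freq) == _round_freq(t.required_ref_freq)
        and m.rob_coverage >= t.min_cov_robur
    ]
    report.n_final = len(survivors)

    return sorted(survivors, key=lambda m: m.key), report
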