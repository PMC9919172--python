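"""Bayesian multilocus assignment to reference groups.

Samples are assigned to the *Q. robur*, *Q. petraea* or hybrid reference
group with the Rannala–Mountain predictive genotype probability. Each locus
carries a symmetric Dirichlet prior with parameter tau = 1/k per allele
(k = number of distinct alleles seen across all panels and the query), so
with panel allele counts n_a (total n) the probability of drawing a
genotype from the group is

    P(a,a) = (n_a + tau)(n_a + tau + 1) / ((n + 1)(n + 2))
    P(a,b) = 2 (n_a + tau)(n_b + tau) / ((n + 1)(n + 2)),  a != b

Loci are treated as independent; the multilocus log-likelihood is the sum
of per-locus log probabilities over the sample's typed loci, skipped
symmetrically in every group when missing. Scores are the normalized
likelihoods across groups (computed in log space).

The exclusion probability guards against false-positive assignment: for a
group it is the proportion of genotypes simulated from the group's
posterior-mean allele frequencies, (n_a + tau)/(n + 1), whose likelihood
under the group strictly exceeds the sample's. Values near 1 mean the
sample is atypical for the group; values below the 0.95 threshold mean a
false-positive assignment is improbable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import (
    Genotype,
    MultilocusGenotype,
    ReferencePanel,
    format_genotype,
)
from .panel import GROUP_HYBRID, GROUP_PETRAEA, GROUP_ROBUR

_TIE_EPS = 1e-9


@dataclass(frozen=True)
class AssignmentConfig:
    prior_style: str = "rannala_mountain"  # tau = 1/k; 'uniform' gives tau = 1
    min_typed: int = 4
    n_sim: int = 10_000
    seed: int = 1
    exclusion_threshold: float = 0.95
    score_decimals: int = 3

    def __post_init__(self) -> None:
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if not 0 < self.exclusion_threshold < 1:
            raise ValueError("exclusion_threshold must lie in (0, 1)")
        if self.prior_style not in ("rannala_mountain", "uniform"):
            raise ValueError(f"unknown prior_style {self.prior_style!r}")


@dataclass
class AssignmentResult:
    sample_id: str
    group: str  # nominal group label of the sample
    scores: dict[str, float]
    exclusion: dict[str, float]
    assigned: str
    ties: list[str] = field(default_factory=list)
    divergent: list[str] = field(default_factory=list)


def _tau(k: int, prior_style: str) -> float:
    return 1.0 / k if prior_style == "rannala_mountain" else 1.0


def predictive_genotype_prob(
    genotype: Genotype,
    counts: Mapping[str, int],
    k: int,
    prior_style: str = "rannala_mountain",
) -> float:
    """Posterior-predictive probability of an unordered genotype.

    *counts* are the panel's allele counts at the locus; *k* the number of
    distinct alleles at the locus across all panels and the query (alleles
    unseen in the panel receive prior mass only).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tau = _tau(k, prior_style)
    total_prior = k * tau
    n = sum(counts.values())
    denom = (n + total_prior) * (n + total_prior + 1)
    a, b = genotype
    na = counts.get(a, 0) + tau
    if a == b:
        return na * (na + 1) / denom
    nb = counts.get(b, 0) + tau
    return 2 * na * nb / denom


def allele_universe(
    panels: Sequence[ReferencePanel],
    queries: Sequence[MultilocusGenotype] = (),
) -> dict[str, tuple[str, ...]]:
    """Distinct alleles per locus across all panels and query samples."""
    universe: dict[str, set[str]] = {}
    for panel in panels:
        for locus in panel.locus_ids:
            universe.setdefault(locus, set()).update(panel.allele_counts(locus))
    for q in queries:
        for locus, g in q.loci.items():
            if g is not None:
                universe.setdefault(locus, set()).update(g)
    return {locus: tuple(sorted(alleles)) for locus, alleles in universe.items()}


def multilocus_log_likelihood(
    g: MultilocusGenotype,
    panel: ReferencePanel,
    universe: Mapping[str, tuple[str, ...]],
    cfg: AssignmentConfig,
    loci: Optional[Sequence[str]] = None,
) -> float:
    """Sum of log predictive probabilities over the sample's typed loci."""
    typed = [l for l in (loci if loci is not None else g.typed_loci)
             if g.loci.get(l) is not None]
    if len(typed) < cfg.min_typed:
        raise ValueError(
            f"sample {g.sample_id!r}: typed at {len(typed)} loci, "
            f"fewer than min_typed={cfg.min_typed}"
        )
    total = 0.0
    for locus in typed:
        counts = panel.allele_counts(locus)
        k = len(universe.get(locus, ())) or len(set(g.loci[locus]))
        total += math.log(
            predictive_genotype_prob(g.loci[locus], counts, k, cfg.prior_style)
        )
    return total


def posterior_mean_freqs(
    counts: Mapping[str, int],
    alleles: Sequence[str],
    prior_style: str = "rannala_mountain",
) -> np.ndarray:
    """Posterior-mean allele frequencies (n_a + tau)/(n + k*tau) over *alleles*."""
    k = len(alleles)
    tau = _tau(k, prior_style)
    n = sum(counts.values())
    return np.array([(counts.get(a, 0) + tau) / (n + k * tau) for a in alleles])


def assignment_scores(
    g: MultilocusGenotype,
    panels: Mapping[str, ReferencePanel],
    cfg: AssignmentConfig,
    universe: Optional[Mapping[str, tuple[str, ...]]] = None,
) -> tuple[dict[str, float], str, list[str]]:
    """Normalized per-group scores, assigned group (argmax) and ties."""
    if not panels:
        raise ValueError("no reference panels supplied")
    if universe is None:
        universe = allele_universe(list(panels.values()), [g])
    logliks = {
        label: multilocus_log_likelihood(g, panel, universe, cfg)
        for label, panel in panels.items()
    }
    peak = max(logliks.values())
    if not math.isfinite(peak):
        raise ValueError(
            f"sample {g.sample_id!r}: all group likelihoods underflow; "
            "inspect the prior and panel counts"
        )
    weights = {label: math.exp(ll - peak) for label, ll in logliks.items()}
    total = sum(weights.values())
    scores = {label: w / total for label, w in weights.items()}
    best = max(scores.values())
    tied = [label for label, s in scores.items() if best - s <= _TIE_EPS]
    assigned = sorted(tied)[0] if len(tied) > 1 else max(scores, key=scores.get)
    return scores, assigned, tied if len(tied) > 1 else []


def _locus_logprob_matrix(
    counts: Mapping[str, int], alleles: Sequence[str], prior_style: str
) -> np.ndarray:
    """log P(genotype{a_i, a_j}) for every allele pair, as a k x k matrix."""
    k = len(alleles)
    mat = np.empty((k, k))
    for i, a in enumerate(alleles):
        for j, b in enumerate(alleles):
            mat[i, j] = math.log(
                predictive_genotype_prob(
                    (a, b) if a <= b else (b, a), counts, k, prior_style
                )
            )
    return mat


def exclusion_probability(
    g: MultilocusGenotype,
    panel: ReferencePanel,
    universe: Mapping[str, tuple[str, ...]],
    cfg: AssignmentConfig,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo exclusion probability of *g* for one reference group.

    Simulates ``cfg.n_sim`` multilocus genotypes at the sample's typed loci
    from the group's posterior-mean allele frequencies and returns the
    proportion with log-likelihood strictly greater than the sample's
    (computed along the identical code path so exact ties are preserved).
    """
    typed = g.typed_loci
    sim_total = np.zeros(cfg.n_sim)
    query_total = 0.0
    for locus in typed:
        alleles = universe.get(locus) or tuple(sorted(set(g.loci[locus])))
        counts = panel.allele_counts(locus)
        mat = _locus_logprob_matrix(counts, alleles, cfg.prior_style)
        freqs = posterior_mean_freqs(counts, alleles, cfg.prior_style)
        idx = {a: i for i, a in enumerate(alleles)}
        a_draw = rng.choice(len(alleles), size=cfg.n_sim, p=freqs)
        b_draw = rng.choice(len(alleles), size=cfg.n_sim, p=freqs)
        sim_total += mat[a_draw, b_draw]
        ga, gb = g.loci[locus]
        query_total += mat[idx[ga], idx[gb]]
    return float(np.mean(sim_total > query_total + _TIE_EPS))


def divergent_marker_report(
    g: MultilocusGenotype,
    panels: Mapping[str, ReferencePanel],
    relative_to: Optional[str] = None,
) -> list[str]:
    """Notes on loci where *g* departs from its group's modal genotype.

    Heterozygous loci are noted as "<region> hetero" ("both <region> hetero"
    when both SNPs of a two-SNP region are heterozygous), missing loci as
    "<region> missing", and loci homozygous for the other species' modal
    allele as "<region> homo QP"/"homo QR". An empty list means the sample
    is fully modal for its group.
    """
    from .panel import default_panel

    group = relative_to or g.group
    pet_panel = panels.get(GROUP_PETRAEA)
    rob_panel = panels.get(GROUP_ROBUR)
    panel_def = default_panel()

    notes_by_region: dict[str, list[str]] = {}
    region_sizes: dict[str, int] = {}
    for marker in panel_def:
        for locus in marker.loci:
            region_sizes[locus.region_number] = (
                region_sizes.get(locus.region_number, 0) + 1
            )
            region = locus.region_number
            if locus.locus_id not in g.loci and locus.locus_id not in {
                l for p in panels.values() for l in p.locus_ids
            }:
                continue
            gt = g.loci.get(locus.locus_id)
            if gt is None:
                notes_by_region.setdefault(region, []).append("missing")
            elif gt[0] != gt[1]:
                notes_by_region.setdefault(region, []).append("hetero")
            else:
                allele = gt[0]
                pet_modal = pet_panel.modal_allele(locus.locus_id) if pet_panel else None
                rob_modal = rob_panel.modal_allele(locus.locus_id) if rob_panel else None
                if group == GROUP_ROBUR and allele == pet_modal and allele != rob_modal:
                    notes_by_region.setdefault(region, []).append("homo QP")
                elif group == GROUP_PETRAEA and allele == rob_modal and allele != pet_modal:
                    notes_by_region.setdefault(region, []).append("homo QR")

    notes = []
    for region in sorted(notes_by_region, key=int):
        for note in sorted(set(notes_by_region[region])):
            count = notes_by_region[region].count(note)
            if note == "hetero" and count == region_sizes.get(region, 1) and count > 1:
                notes.append(f"both {region} {note}")
            else:
                notes.append(f"{region} {note}")
    return notes


def assign_sample(
    g: MultilocusGenotype,
    panels: Mapping[str, ReferencePanel],
    cfg: AssignmentConfig,
    rng: np.random.Generator,
    universe: Optional[Mapping[str, tuple[str, ...]]] = None,
    compute_exclusion: bool = True,
) -> AssignmentResult:
    """Score one sample against every panel; full Tables-4/5/6 style row."""
    if universe is None:
        universe = allele_universe(list(panels.values()), [g])
    scores, assigned, ties = assignment_scores(g, panels, cfg, universe)
    exclusion = {}
    if compute_exclusion:
        for label, panel in panels.items():
            exclusion[label] = exclusion_probability(g, panel, universe, cfg, rng)
    relative = g.group if g.group in (GROUP_ROBUR, GROUP_PETRAEA, GROUP_HYBRID) else assigned
    divergent = divergent_marker_report(g, panels, relative_to=relative)
    return AssignmentResult(
        sample_id=g.sample_id,
        group=g.group,
        scores=scores,
        exclusion=exclusion,
        assigned=assigned,
        ties=ties,
        divergent=divergent,
    )


def assign_samples(
    queries: Sequence[MultilocusGenotype],
    panels: Mapping[str, ReferencePanel],
    cfg: AssignmentConfig,
    compute_exclusion: bool = True,
) -> list[AssignmentResult]:
    """Assign a batch of query samples (seeded, order-stable)."""
    universe = allele_universe(list(panels.values()), queries)
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(queries))
    results = []
    for q, ss in zip(queries, seeds):
        rng = np.random.default_rng(ss)
        results.append(
            assign_sample(q, panels, cfg, rng, universe, compute_exclusion)
        )
    return results


def self_assignment(
    panels: Mapping[str, ReferencePanel],
    cfg: AssignmentConfig,
    leave_one_out: bool = True,
    groups: Optional[Sequence[str]] = None,
    compute_exclusion: bool = True,
) -> tuple[list[AssignmentResult], dict[str, dict[str, int]]]:
    """Self-assignment test of every panel member (optionally leave-one-out).

    Members typed at fewer than ``cfg.min_typed`` loci (e.g. individuals
    genotyped only at the InDel marker) are skipped. Returns the per-sample
    results and a summary {true group: {assigned group: count}}.
    """
    results = []
    summary: dict[str, dict[str, int]] = {}
    test_groups = list(groups) if groups is not None else list(panels)
    samples = [
        m for label in test_groups for m in panels[label].members
        if m.n_typed >= cfg.min_typed
    ]
    seeds = np.random.SeedSequence(cfg.seed).spawn(max(len(samples), 1))
    universe = allele_universe(list(panels.values()))
    for member, ss in zip(samples, seeds):
        label = member.group
        if leave_one_out:
            if len(panels[label]) < 2:
                raise ValueError(
                    f"panel {label!r} has fewer than 2 members; cannot leave one out"
                )
            test_panels = dict(panels)
            test_panels[label] = panels[label].without(member.sample_id)
        else:
            test_panels = dict(panels)
        rng = np.random.default_rng(ss)
        res = assign_sample(
            member, test_panels, cfg, rng, universe, compute_exclusion
        )
        results.append(res)
        summary.setdefault(label, {})
        summary[label][res.assigned] = summary[label].get(res.assigned, 0) + 1
    return results, summary


# ---------------------------------------------------------------------------
# panel summary


def summarize_panel(panel: ReferencePanel) -> pd.DataFrame:
    """Genotype-class percentage table per locus (integer-rounded).

    Columns: locus, genotype, count, n, percent -- the per-locus N excludes
    missing genotypes.
    """
    if not panel.members:
        raise ValueError(f"panel {panel.group!r} is empty")
    rows = []
    for locus in panel.locus_ids:
        classes: dict[str, int] = {}
        for m in panel.members:
            g = m.loci.get(locus)
            if g is not None:
                label = format_genotype(g)
                classes[label] = classes.get(label, 0) + 1
        n = sum(classes.values())
        for label, count in sorted(
            classes.items(), key=lambda kv: (-kv[1], kv[0])
        ):
            rows.append(
                {
                    "locus": locus,
                    "genotype": label,
                    "count": count,
                    "n": n,
                    "percent": round(100.0 * count / n),
                }
            )
    return pd.DataFrame(rows, columns=["locus", "genotype", "count", "n", "percent"])


def results_table(results: Sequence[AssignmentResult], cfg: AssignmentConfig) -> pd.DataFrame:
    """Render assignment results in the reported-table layout."""
    d = cfg.score_decimals
    rows = []
    for r in results:
        divergent = "; ".join(r.divergent) if r.divergent else f"all {r.assigned}"
        if r.ties:
            divergent += f" [tied: {', '.join(sorted(r.ties))}]"
        rows.append(
            {
                "Sample": r.sample_id,
                "Group": r.group,
                "Score_QUPET": round(r.scores.get(GROUP_PETRAEA, 0.0), d),
                "Score_QUROB": round(r.scores.get(GROUP_ROBUR, 0.0), d),
                "Score_Hybrid": round(r.scores.get(GROUP_HYBRID, 0.0), d),
                "Excl_QUPET": round(r.exclusion.get(GROUP_PETRAEA, float("nan")), d),
                "Excl_QUROB": round(r.exclusion.get(GROUP_ROBUR, float("nan")), d),
                "Excl_Hybrid": round(r.exclusion.get(GROUP_HYBRID, float("nan")), d),
                "Assigned": r.assigned,
                "Divergent": divergent,
            }
        )
    return pd.DataFrame(rows)
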