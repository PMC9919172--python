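"""The Bayesian assignment engine: predictive probabilities, scores,
exclusion probabilities, self-assignment and reports."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import kstest

from oakdiff.assign import (
    AssignmentConfig,
    allele_universe,
    assignment_scores,
    divergent_marker_report,
    exclusion_probability,
    multilocus_log_likelihood,
    posterior_mean_freqs,
    predictive_genotype_prob,
    self_assignment,
    summarize_panel,
)
from oakdiff.genotypes import MultilocusGenotype, ReferencePanel, make_genotype
from oakdiff.panel import GROUP_HYBRID, GROUP_PETRAEA, GROUP_ROBUR
from oakdiff.simulate import simulate_pure


def panel_of(counts_per_locus: dict[str, dict[str, int]], group="G") -> ReferencePanel:
    """Build a panel of homozygotes/heterozygotes realizing given allele counts."""
    members = []
    loci = list(counts_per_locus)
    # expand counts to per-locus allele lists and pair them into genotypes
    allele_lists = {
        l: [a for a, c in counts.items() for _ in range(c)]
        for l, counts in counts_per_locus.items()
    }
    n_members = max(len(v) for v in allele_lists.values()) // 2
    for i in range(n_members):
        g = {}
        for l in loci:
            pair = allele_lists[l][2 * i : 2 * i + 2]
            if len(pair) == 2:
                g[l] = make_genotype(*pair)
        members.append(MultilocusGenotype(f"{group}_{i}", group, g))
    return ReferencePanel(group, members)


class TestPredictiveProbability:
    def test_closed_form_homozygote(self):
        # k=2, counts {A:10, B:0}: P(AA) = 10.5 * 11.5 / (11 * 12)
        assert predictive_genotype_prob(("A", "A"), {"A": 10, "B": 0}, 2) == (
            pytest.approx(0.914773, abs=5e-7)
        )

    def test_closed_form_heterozygote(self):
        assert predictive_genotype_prob(("A", "B"), {"A": 10, "B": 0}, 2) == (
            pytest.approx(0.079545, abs=5e-7)
        )

    def test_unseen_allele_gets_prior_mass_only(self):
        p = predictive_genotype_prob(("C", "C"), {"A": 10}, 2)
        assert p == pytest.approx(0.5 * 1.5 / (11 * 12))

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_sums_to_one_over_all_genotypes(self, k):
        rng = np.random.default_rng(k)
        alleles = [chr(65 + i) for i in range(k)]
        for _ in range(10):
            counts = {a: int(rng.integers(0, 31)) for a in alleles}
            total = sum(
                predictive_genotype_prob(make_genotype(a, b), counts, k)
                for a, b in itertools.combinations_with_replacement(alleles, 2)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_adding_observed_copy_increases_homozygote_prob(self):
        for n_a in range(0, 30):
            p1 = predictive_genotype_prob(("A", "A"), {"A": n_a, "B": 5}, 2)
            p2 = predictive_genotype_prob(("A", "A"), {"A": n_a + 1, "B": 5}, 2)
            assert p2 > p1


def _dirichlet_multinomial_oracle(genotype, counts, k):
    """Independent gammaln-based Dirichlet-multinomial predictive term."""
    tau = 1.0 / k
    n = sum(counts.values())
    add = {}
    for a in genotype:
        add[a] = add.get(a, 0) + 1
    mult = 2 if genotype[0] != genotype[1] else 1
    log_p = gammaln(n + k * tau) - gammaln(n + 2 + k * tau)
    for a, extra in add.items():
        na = counts.get(a, 0) + tau
        log_p += gammaln(na + extra) - gammaln(na)
    return mult * math.exp(float(log_p))


class TestMultilocusLikelihood:
    def test_matches_dirichlet_multinomial_oracle(self):
        rng = np.random.default_rng(8)
        cfg = AssignmentConfig(min_typed=1)
        for _ in range(25):
            k = int(rng.integers(2, 5))
            alleles = [chr(65 + i) for i in range(k)]
            loci = [f"L{j}" for j in range(int(rng.integers(1, 5)))]
            counts = {
                l: {a: int(rng.integers(0, 20)) for a in alleles} for l in loci
            }
            panel = panel_of(counts)
            g = MultilocusGenotype(
                "q",
                "unknown",
                {
                    l: make_genotype(
                        alleles[rng.integers(k)], alleles[rng.integers(k)]
                    )
                    for l in loci
                },
            )
            universe = {l: tuple(alleles) for l in loci}
            ll = multilocus_log_likelihood(g, panel, universe, cfg)
            expected = sum(
                math.log(
                    _dirichlet_multinomial_oracle(
                        g.loci[l], panel.allele_counts(l), k
                    )
                )
                for l in loci
            )
            assert ll == pytest.approx(expected, rel=1e-9)

    def test_min_typed_enforced(self):
        cfg = AssignmentConfig(min_typed=4)
        panel = panel_of({f"L{i}": {"A": 4} for i in range(6)})
        g = MultilocusGenotype(
            "q", "unknown", {"L0": ("A", "A"), "L1": ("A", "A"), "L2": ("A", "A")}
        )
        with pytest.raises(ValueError, match="min_typed"):
            multilocus_log_likelihood(g, panel, {}, cfg)


class TestAssignmentScores:
    def test_identical_panels_score_one_third(self):
        counts = {f"L{i}": {"A": 10, "B": 10} for i in range(4)}
        panels = {
            "P1": panel_of(counts, "P1"),
            "P2": panel_of(counts, "P2"),
            "P3": panel_of(counts, "P3"),
        }
        g = MultilocusGenotype(
            "q", "unknown", {f"L{i}": ("A", "B") for i in range(4)}
        )
        scores, assigned, ties = assignment_scores(
            g, panels, AssignmentConfig(min_typed=1)
        )
        for s in scores.values():
            assert s == pytest.approx(1 / 3)
        assert sorted(ties) == ["P1", "P2", "P3"]

    def test_two_panel_single_locus_closed_form(self):
        panels = {
            "P1": panel_of({"L0": {"A": 10, "B": 0}}, "P1"),
            "P2": panel_of({"L0": {"A": 0, "B": 10}}, "P2"),
        }
        g = MultilocusGenotype("q", "unknown", {"L0": ("A", "A")})
        scores, assigned, _ = assignment_scores(
            g, panels, AssignmentConfig(min_typed=1)
        )
        assert scores["P1"] == pytest.approx(0.99383, abs=5e-6)
        assert scores["P2"] == pytest.approx(0.00617, abs=5e-6)
        assert assigned == "P1"

    def test_scores_sum_to_one_and_permutation_invariant(self, ref_panels, petraea_modal):
        cfg = AssignmentConfig()
        scores, _, _ = assignment_scores(petraea_modal, ref_panels, cfg)
        assert sum(scores.values()) == pytest.approx(1.0)
        reordered = dict(reversed(list(ref_panels.items())))
        scores2, _, _ = assignment_scores(petraea_modal, reordered, cfg)
        assert scores2 == pytest.approx(scores)

    def test_petraea_modal_genotype_assigned_to_petraea(self, ref_panels, petraea_modal):
        scores, assigned, _ = assignment_scores(
            petraea_modal, ref_panels, AssignmentConfig()
        )
        assert assigned == GROUP_PETRAEA
        assert scores[GROUP_PETRAEA] > 0.99
        assert round(scores[GROUP_ROBUR], 3) == 0.0


class TestExclusionProbability:
    def test_monomorphic_panel_gives_zero(self):
        panel = panel_of({f"L{i}": {"A": 20} for i in range(4)})
        g = MultilocusGenotype("q", "unknown", {f"L{i}": ("A", "A") for i in range(4)})
        universe = allele_universe([panel], [g])
        p = exclusion_probability(
            g, panel, universe, AssignmentConfig(n_sim=500, min_typed=1),
            np.random.default_rng(0),
        )
        assert p == 0.0

    def test_unseen_alleles_are_excluded(self):
        panel = panel_of({f"L{i}": {"A": 20, "B": 2} for i in range(6)})
        g = MultilocusGenotype("q", "unknown", {f"L{i}": ("Z", "Z") for i in range(6)})
        universe = allele_universe([panel], [g])
        p = exclusion_probability(
            g, panel, universe, AssignmentConfig(n_sim=2000, min_typed=1),
            np.random.default_rng(0),
        )
        assert p >= 0.99

    def test_seeded_reproducibility(self, ref_panels, petraea_modal):
        cfg = AssignmentConfig(n_sim=500)
        universe = allele_universe(list(ref_panels.values()), [petraea_modal])
        p1 = exclusion_probability(
            petraea_modal, ref_panels[GROUP_PETRAEA], universe, cfg,
            np.random.default_rng(99),
        )
        p2 = exclusion_probability(
            petraea_modal, ref_panels[GROUP_PETRAEA], universe, cfg,
            np.random.default_rng(99),
        )
        assert p1 == p2

    def test_panel_drawn_queries_are_uniform(self):
        # probability-integral-transform: exclusion probabilities of queries
        # drawn from the panel's own frequencies are ~ Uniform(0, 1)
        rng = np.random.default_rng(7)
        freqs = [0.15, 0.25, 0.35, 0.45, 0.55, 0.65]
        members = []
        for i in range(60):
            loci = {
                f"L{j}": make_genotype(*rng.choice(["A", "B"], 2, p=[f, 1 - f]))
                for j, f in enumerate(freqs)
            }
            members.append(MultilocusGenotype(f"m{i}", "G", loci))
        panel = ReferencePanel("G", members)
        universe = allele_universe([panel])
        cfg = AssignmentConfig(n_sim=400, min_typed=4)
        loci = [f"L{j}" for j in range(6)]
        values = []
        for i in range(250):
            q = simulate_pure(rng, panel, f"q{i}", loci)
            values.append(exclusion_probability(q, panel, universe, cfg, rng))
        values = np.asarray(values)
        assert abs(values.mean() - 0.5) < 0.05
        assert kstest(values, "uniform").pvalue > 1e-3


class TestSelfAssignment:
    def test_all_simulated_f1_hybrids_assigned_to_hybrid(self, ref_panels):
        cfg = AssignmentConfig(seed=1, n_sim=500)
        results, summary = self_assignment(
            ref_panels, cfg, leave_one_out=True, groups=[GROUP_HYBRID]
        )
        assert summary == {GROUP_HYBRID: {GROUP_HYBRID: 20}}
        for r in results:
            assert r.scores[GROUP_HYBRID] > 0.5

    def test_leave_one_out_needs_two_members(self):
        lone = {
            "G": ReferencePanel(
                "G",
                [
                    MultilocusGenotype(
                        "only", "G", {f"L{i}": ("A", "A") for i in range(4)}
                    )
                ],
            )
        }
        with pytest.raises(ValueError, match="fewer than 2"):
            self_assignment(lone, AssignmentConfig(min_typed=1), leave_one_out=True)

    def test_clone_panel_members_score_home(self):
        clones = panel_of({f"L{i}": {"A": 20} for i in range(4)}, "HOME")
        far1 = panel_of({f"L{i}": {"B": 20} for i in range(4)}, "FAR1")
        far2 = panel_of({f"L{i}": {"C": 20} for i in range(4)}, "FAR2")
        panels = {"HOME": clones, "FAR1": far1, "FAR2": far2}
        results, summary = self_assignment(
            panels, AssignmentConfig(min_typed=1, n_sim=10), leave_one_out=True
        )
        assert all(r.assigned == r.group for r in results)
        for r in results:
            if r.group == "HOME":
                assert r.scores["HOME"] > 0.99

    def test_pure_species_misassignment_rate_low(self, ref_panels):
        # pure genotypes simulated from the reconstructed panels are almost
        # always assigned home
        rng = np.random.default_rng(21)
        loci = ref_panels[GROUP_ROBUR].locus_ids
        queries = []
        for i in range(100):
            queries.append(
                simulate_pure(rng, ref_panels[GROUP_ROBUR], f"r{i}", loci, GROUP_ROBUR)
            )
            queries.append(
                simulate_pure(rng, ref_panels[GROUP_PETRAEA], f"p{i}", loci, GROUP_PETRAEA)
            )
        cfg = AssignmentConfig(min_typed=4)
        wrong = 0
        for q in queries:
            _, assigned, _ = assignment_scores(q, ref_panels, cfg)
            other = {GROUP_ROBUR: GROUP_PETRAEA, GROUP_PETRAEA: GROUP_ROBUR}[q.group]
            wrong += assigned == other
        assert wrong / len(queries) < 0.05


class TestSummaries:
    def test_genotype_class_percentages(self, ref_panels):
        df = summarize_panel(ref_panels[GROUP_PETRAEA])
        row = df[
            (df.locus == "QP_miSeq14a_SNP1") & (df.genotype == "C/C")
        ].iloc[0]
        assert (row["count"], row["n"], row["percent"]) == (38, 45, 84)
        row = df[(df.locus == "QP_miSeq14a_SNP1") & (df.genotype == "C/T")].iloc[0]
        assert row["percent"] == 16

    def test_robur_monomorphic_rows(self, ref_panels):
        df = summarize_panel(ref_panels[GROUP_ROBUR])
        row = df[df.locus == "QP_miSeq14a_SNP1"]
        assert list(row.genotype) == ["T/T"] and list(row.percent) == [100]

    def test_single_member_panel(self):
        panel = ReferencePanel(
            "G", [MultilocusGenotype("s", "G", {"L0": ("A", "B")})]
        )
        df = summarize_panel(panel)
        assert list(df.percent) == [100]

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_panel(ReferencePanel("G", []))


class TestDivergentMarkers:
    def test_heterozygous_locus_noted(self, ref_panels):
        g = MultilocusGenotype(
            "s",
            GROUP_PETRAEA,
            {
                "QP_miSeq14a_SNP1": ("C", "C"),
                "QP_miSeq14a_SNP2": ("T", "T"),
                "QP_miSeq32_InDel": ("193", "193"),
                "QP_miSeq36_SNP": ("C", "T"),
                "QP_miSeq38_SNP1": ("A", "A"),
                "QP_miSeq38_SNP2": ("C", "C"),
            },
        )
        assert divergent_marker_report(g, ref_panels) == ["36 hetero"]

    def test_fully_modal_genotype_is_empty(self, ref_panels):
        g = MultilocusGenotype(
            "s",
            GROUP_ROBUR,
            {
                "QP_miSeq14a_SNP1": ("T", "T"),
                "QP_miSeq14a_SNP2": ("C", "C"),
                "QP_miSeq32_InDel": ("188", "188"),
                "QP_miSeq36_SNP": ("T", "T"),
                "QP_miSeq38_SNP1": ("G", "G"),
                "QP_miSeq38_SNP2": ("A", "A"),
            },
        )
        assert divergent_marker_report(g, ref_panels) == []

    def test_missing_region_noted(self, ref_panels):
        g = MultilocusGenotype(
            "s",
            GROUP_ROBUR,
            {
                "QP_miSeq14a_SNP1": None,
                "QP_miSeq14a_SNP2": None,
                "QP_miSeq32_InDel": ("188", "188"),
                "QP_miSeq36_SNP": ("T", "T"),
                "QP_miSeq38_SNP1": ("G", "G"),
                "QP_miSeq38_SNP2": ("A", "A"),
            },
        )
        assert divergent_marker_report(g, ref_panels) == ["14 missing"]

    def test_homozygous_for_other_species_allele(self, ref_panels):
        g = MultilocusGenotype(
            "s",
            GROUP_PETRAEA,
            {
                "QP_miSeq14a_SNP1": ("C", "C"),
                "QP_miSeq14a_SNP2": ("T", "T"),
                "QP_miSeq32_InDel": ("193", "193"),
                "QP_miSeq36_SNP": ("T", "T"),
                "QP_miSeq38_SNP1": ("A", "A"),
                "QP_miSeq38_SNP2": ("C", "C"),
            },
        )
        assert divergent_marker_report(g, ref_panels) == ["36 homo QR"]

    def test_both_snps_heterozygous_collapsed(self, ref_panels):
        g = MultilocusGenotype(
            "s",
            GROUP_ROBUR,
            {
                "QP_miSeq14a_SNP1": ("T", "T"),
                "QP_miSeq14a_SNP2": ("C", "C"),
                "QP_miSeq32_InDel": ("188", "188"),
                "QP_miSeq36_SNP": ("T", "T"),
                "QP_miSeq38_SNP1": ("A", "G"),
                "QP_miSeq38_SNP2": ("A", "C"),
            },
        )
        assert divergent_marker_report(g, ref_panels) == ["both 38 hetero"]


class TestConfigValidation:
    def test_bad_nsim(self):
        with pytest.raises(ValueError):
            AssignmentConfig(n_sim=0)

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            AssignmentConfig(exclusion_threshold=1.5)

    def test_posterior_mean_freqs_normalized(self):
        f = posterior_mean_freqs({"A": 10, "B": 3}, ("A", "B", "C"))
        assert f.sum() == pytest.approx(1.0)
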