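import pytest

from oakdiff.genotypes import MultilocusGenotype
from oakdiff.panel import GROUP_PETRAEA, default_panel
from oakdiff.simulate import PanelConfig, make_marker_templates, make_reference_panels


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def templates(panel):
    """Seeded marker templates keyed by (region, allele)."""
    return {
        (t.marker_id, t.species_allele): t
        for t in make_marker_templates(1, panel)
    }


@pytest.fixture(scope="session")
def ref_panels():
    """Reconstructed QUROB/QUPET panels plus the seeded F1 hybrid panel."""
    return make_reference_panels(PanelConfig(seed=1))


@pytest.fixture()
def petraea_modal():
    """Genotype homozygous for every petraea-typical allele at all six loci."""
    return MultilocusGenotype(
        "QUPET_316",
        GROUP_PETRAEA,
        {
            "QP_miSeq14a_SNP1": ("C", "C"),
            "QP_miSeq14a_SNP2": ("T", "T"),
            "QP_miSeq32_InDel": ("193", "193"),
            "QP_miSeq36_SNP": ("C", "C"),
            "QP_miSeq38_SNP1": ("A", "A"),
            "QP_miSeq38_SNP2": ("C", "C"),
        },
    )
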