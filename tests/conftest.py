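"""Shared fixtures: the printed worked-example matrices and a planted cohort."""

import pytest

import omicrules as om

# Worked example: the published RNA-seq / methylation example matrices for
# breast cancer (three genes, aliquot-barcode rows).  Class labels are passed
# explicitly because the printed example labels one 01A aliquot "Normal",
# contradicting barcode semantics.

RNA_ROWS = {
    "TCGA-A1-A0SD-01A-11R-A115-07": {"GDA": 0.6, "SCN3A": 28.4, "SCN3B": 43.6},
    "TCGA-A7-A4SD-01A-11R-A266-07": {"GDA": 0.0, "SCN3A": 6.4, "SCN3B": 1.9},
}
RNA_LABELS = {
    "TCGA-A1-A0SD-01A-11R-A115-07": "normal",
    "TCGA-A7-A4SD-01A-11R-A266-07": "tumoral",
}
METH_ROWS = {
    "TCGA-A7-A4SD-01A-11D-A268-05": {"GDA": 1.6, "SCN3A": 2.3, "SCN3B": 2.0},
    "TCGA-GI-A2C9-01A-11D-A21R-05": {"GDA": 1.9, "SCN3A": 2.7, "SCN3B": 2.3},
}
METH_LABELS = {
    "TCGA-A7-A4SD-01A-11D-A268-05": "tumoral",
    "TCGA-GI-A2C9-01A-11D-A21R-05": "tumoral",
}


@pytest.fixture
def rna_example() -> om.GeneMatrix:
    return om.build_matrix(RNA_ROWS, RNA_LABELS, "rnaSeq")


@pytest.fixture
def meth_example() -> om.GeneMatrix:
    return om.build_matrix(METH_ROWS, METH_LABELS, "dnaMeth")


@pytest.fixture(scope="session")
def study_cohort():
    """Planted-signal cohort at study-condition defaults: 100+100 samples,
    500 genes, 10 planted genes, per-site effect 0.5 on the beta scale."""
    return om.simulate_cohort(om.CohortSpec(seed=1))


@pytest.fixture(scope="session")
def study_combined(study_cohort) -> om.GeneMatrix:
    _, _, combined = om.matrices_from_cohort(study_cohort)
    return combined


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for unit-level pipeline tests."""
    return om.simulate_cohort(
        om.CohortSpec(n_tumoral=15, n_normal=15, n_genes=30, seed=5)
    )
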