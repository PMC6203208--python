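"""Gene-level aggregation and matrix assembly/serialization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import omicrules as om
from omicrules.gene_matrix import MISSING_TOKEN
from omicrules.tcga_io import FileFormatError, MethylationSiteRecord


def site(gene, beta, pos=100):
    return MethylationSiteRecord("chr1", pos, pos + 1, "+", gene, beta)


class TestAggregateMethylation:
    def test_sum_of_betas(self):
        records = [site("GDA", b, pos=100 + i) for i, b in enumerate([0.4, 0.7, 0.5])]
        assert om.aggregate_methylation(records) == {"GDA": pytest.approx(1.6)}

    def test_zero_beta_gene_is_present(self):
        assert om.aggregate_methylation([site("GDA", 0.0)]) == {"GDA": 0.0}

    def test_missing_beta_and_unannotated_sites_skipped(self):
        records = [site("GDA", 0.3), site("GDA", None), site("", 0.9)]
        assert om.aggregate_methylation(records) == {"GDA": pytest.approx(0.3)}

    def test_composite_symbol_credits_every_gene(self):
        totals = om.aggregate_methylation([site("A;B", 0.5), site("B", 0.25)])
        assert totals == {"A": pytest.approx(0.5), "B": pytest.approx(0.75)}

    def test_matches_fold_by_addition_oracle(self):
        rng = np.random.default_rng(42)
        betas = rng.uniform(0, 1, size=50)
        records = [site("GDA", float(b), pos=100 + i) for i, b in enumerate(betas)]
        expected = 0.0
        for b in betas:  # independent fold-by-addition oracle
            expected = expected + float(b)
        assert om.aggregate_methylation(records)["GDA"] == pytest.approx(
            expected, abs=1e-12
        )

    @settings(max_examples=50, derandomize=True)
    @given(
        betas=st.lists(
            st.floats(0, 1, allow_nan=False), min_size=0, max_size=20
        ),
        perm_seed=st.integers(0, 1000),
    )
    def test_permutation_invariant_and_conserving(self, betas, perm_seed):
        genes = ["A", "B", "C"]
        records = [
            site(genes[i % 3], b, pos=100 + i) for i, b in enumerate(betas)
        ]
        rng = np.random.default_rng(perm_seed)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        a = om.aggregate_methylation(records)
        b = om.aggregate_methylation(shuffled)
        assert set(a) == set(b)
        for g in a:
            assert a[g] == pytest.approx(b[g], abs=1e-9)
        # conservation: per-gene totals sum to the total annotated beta mass
        assert sum(a.values()) == pytest.approx(sum(betas), abs=1e-9)

    def test_adding_a_site_never_decreases_its_gene(self):
        base = [site("GDA", 0.2), site("GDA", 0.3, pos=200)]
        before = om.aggregate_methylation(base)["GDA"]
        after = om.aggregate_methylation(base + [site("GDA", 0.9, pos=300)])["GDA"]
        assert after >= before


class TestBuildMatrix:
    def test_union_of_gene_sets_with_missing_fill(self):
        m = om.build_matrix(
            {"s1": {"A": 1.0, "B": 2.0}, "s2": {"B": 3.0, "C": 4.0}},
            {"s1": "tumoral", "s2": "normal"},
            "dnaMeth",
        )
        assert m.features == ["A", "B", "C"]
        assert math.isnan(m.data.loc["s1", "C"])
        assert math.isnan(m.data.loc["s2", "A"])

    def test_zero_fill_policy(self):
        m = om.build_matrix(
            {"s1": {"A": 1.0}, "s2": {"B": 2.0}},
            {"s1": "tumoral", "s2": "normal"},
            "rnaSeq",
            fill="zero",
        )
        assert m.data.loc["s1", "B"] == 0.0

    def test_reproduces_printed_expression_grid(self, rna_example):
        assert rna_example.features == ["GDA", "SCN3A", "SCN3B"]
        assert rna_example.data.loc[
            "TCGA-A1-A0SD-01A-11R-A115-07"
        ].tolist() == pytest.approx([0.6, 28.4, 43.6])
        assert rna_example.data.loc[
            "TCGA-A7-A4SD-01A-11R-A266-07"
        ].tolist() == pytest.approx([0.0, 6.4, 1.9])

    def test_empty_input(self):
        m = om.build_matrix({}, {}, "dnaMeth")
        assert (m.n, m.m) == (0, 0)

    def test_missing_label_names_sample(self):
        with pytest.raises(ValueError, match="s2"):
            om.build_matrix({"s1": {"A": 1.0}, "s2": {"A": 2.0}}, {"s1": "tumoral"})


class TestMatrixRoundTrip:
    def make(self):
        df = pd.DataFrame(
            [[1.6, 2.3, np.nan], [0.0, 6.4, 1.9], [1.9, np.nan, 2.3]],
            index=["s1", "s2", "s3"],
            columns=["GDA", "SCN3A", "SCN3B"],
        )
        classes = pd.Series(["tumoral", "normal", "tumoral"], index=df.index)
        return om.GeneMatrix(df, classes, "dnaMeth")

    def test_round_trip_identity_with_missing_entry(self, tmp_path):
        m = self.make()
        path = tmp_path / "m.csv"
        om.write_matrix(m, path)
        again = om.read_matrix(path, "dnaMeth")
        assert again.equals(m)

    def test_header_layout_and_missing_token(self, tmp_path):
        path = tmp_path / "m.csv"
        om.write_matrix(self.make(), path)
        lines = path.read_text().splitlines()
        assert lines[0] == "Sample_ID,GDA,SCN3A,SCN3B,Class"
        assert lines[1] == f"s1,1.6,2.3,{MISSING_TOKEN},tumoral"

    def test_ragged_row_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("Sample_ID,A,B,Class\ns1,1.0,tumoral\n")
        with pytest.raises(FileFormatError, match=":2"):
            om.read_matrix(path)

    def test_duplicate_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("Sample_ID,A,A,Class\ns1,1.0,2.0,tumoral\n")
        with pytest.raises(FileFormatError, match="duplicate"):
            om.read_matrix(path)
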