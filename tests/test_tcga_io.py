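"""Barcode parsing/truncation/class mapping and per-sample file readers."""

import pytest
from hypothesis import given, settings, strategies as st

import omicrules as om
from omicrules.tcga_io import (
    BarcodeError,
    FileFormatError,
    METHYLATION_DIALECT,
    UnsupportedSampleError,
    dialect_from_config,
)


class TestBarcode:
    def test_parse_full_aliquot(self):
        b = om.parse_barcode("TCGA-A7-A4SD-01A-11D-A268-05")
        assert (b.project, b.tss, b.participant, b.sample_vial) == (
            "TCGA", "A7", "A4SD", "01A",
        )
        assert (b.portion_analyte, b.plate, b.center) == ("11D", "A268", "05")

    def test_parse_truncated_form(self):
        b = om.parse_barcode("TCGA-A1-A0SD-01A")
        assert b.sample_vial == "01A"
        assert b.portion_analyte == b.plate == b.center == ""

    @pytest.mark.parametrize(
        "bad",
        ["TCGA-A7", "TCGA", "TCGA-A7-A4SD-XXA", "TCGA-A7-A4SD-99A",
         "TCGA-A7-A4SD-01A-11D-A268-05-EXTRA-F"],
    )
    def test_malformed_barcodes_raise(self, bad):
        with pytest.raises(BarcodeError):
            om.parse_barcode(bad)

    @pytest.mark.parametrize(
        "aliquot,expected",
        [
            ("TCGA-A7-A4SD-01A-11D-A268-05", "TCGA-A7-A4SD-01A"),
            ("TCGA-GI-A2C9-01A-11D-A21R-05", "TCGA-GI-A2C9-01A"),
        ],
    )
    def test_truncate_drops_experiment_fields(self, aliquot, expected):
        truncated = om.truncate_barcode(om.parse_barcode(aliquot))
        assert truncated == expected
        assert aliquot.startswith(truncated)
        assert truncated.count("-") == 3

    def test_truncate_idempotent(self):
        once = om.truncate_id("TCGA-A7-A4SD-01A-11D-A268-05")
        assert om.truncate_id(once) == once

    @pytest.mark.parametrize(
        "vial,expected", [("01A", "tumoral"), ("06A", "tumoral"), ("11A", "normal")]
    )
    def test_class_from_sample_type_code(self, vial, expected):
        b = om.parse_barcode(f"TCGA-A7-A4SD-{vial}")
        assert om.class_from_barcode(b) == expected

    def test_control_codes_unsupported(self):
        b = om.parse_barcode("TCGA-A7-A4SD-20A")
        with pytest.raises(UnsupportedSampleError):
            om.class_from_barcode(b)

    @settings(max_examples=100, derandomize=True)
    @given(
        tss=st.text("ABC0123456789", min_size=2, max_size=2),
        participant=st.text("ABCDEF0123456789", min_size=4, max_size=4),
        code=st.integers(1, 29),
        n_extra=st.integers(0, 3),
    )
    def test_parse_format_round_trip(self, tss, participant, code, n_extra):
        extra = ["11D", "A268", "05"][:n_extra]
        s = "-".join(["TCGA", tss, participant, f"{code:02d}A", *extra])
        assert str(om.parse_barcode(s)) == s


class TestMethylationReader:
    def write(self, tmp_path, lines):
        path = tmp_path / "sample.bed"
        path.write_text("".join(line + "\n" for line in lines))
        return path

    def test_reads_records(self, tmp_path):
        path = self.write(tmp_path, ["chr9\t74720709\t74720710\t.\tGDA\t0.41"])
        (rec,) = om.read_methylation_file(path)
        assert rec.chrom == "chr9" and rec.gene_symbol == "GDA"
        assert rec.beta == pytest.approx(0.41)
        assert (rec.start, rec.end, rec.strand) == (74720709, 74720710, ".")

    def test_empty_file(self, tmp_path):
        assert om.read_methylation_file(self.write(tmp_path, [])) == []

    @pytest.mark.parametrize("token", ["NA", ".", "?"])
    def test_missing_beta_retained(self, tmp_path, token):
        path = self.write(tmp_path, [f"chr1\t10\t11\t+\tGDA\t{token}"])
        (rec,) = om.read_methylation_file(path)
        assert rec.beta is None

    def test_wrong_column_count_names_line(self, tmp_path):
        path = self.write(
            tmp_path, ["chr1\t10\t11\t+\tGDA\t0.5", "chr1\t20\t21\t+\tGDA"]
        )
        with pytest.raises(FileFormatError, match=":2"):
            om.read_methylation_file(path)

    def test_beta_out_of_range_rejected(self, tmp_path):
        path = self.write(tmp_path, ["chr1\t10\t11\t+\tGDA\t1.5"])
        with pytest.raises(FileFormatError):
            om.read_methylation_file(path)

    def test_betas_from_well_formed_file_lie_in_unit_interval(self, tmp_path):
        lines = [f"chr1\t{10+i}\t{11+i}\t+\tG{i}\t0.{i}" for i in range(10)]
        records = om.read_methylation_file(self.write(tmp_path, lines))
        assert all(0.0 <= r.beta <= 1.0 for r in records)

    def test_custom_dialect(self, tmp_path):
        cfg = {
            "columns": {"gene_symbol": 0, "beta": 1, "chrom": 2, "start": 3,
                        "end": 4, "strand": 5},
            "separator": "\t",
            "missing_tokens": ["NULL"],
        }
        dialect = dialect_from_config(cfg)
        path = self.write(tmp_path, ["GDA\tNULL\tchr1\t5\t6\t+"])
        (rec,) = om.read_methylation_file(path, dialect)
        assert rec.beta is None and rec.gene_symbol == "GDA"

    def test_dialect_from_yaml_file(self, tmp_path):
        cfg = tmp_path / "dialect.yaml"
        cfg.write_text("columns:\n  gene_symbol: 0\n  value: 1\nseparator: \"\\t\"\n")
        d = dialect_from_config(cfg)
        assert d.width == 2


class TestExpressionReader:
    def test_reads_gene_value(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("GDA\t0.6\n")
        (rec,) = om.read_expression_file(path)
        assert rec.gene_symbol == "GDA" and rec.value == pytest.approx(0.6)

    def test_duplicate_gene_is_ambiguous(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("GDA\t0.6\nGDA\t0.7\n")
        with pytest.raises(FileFormatError, match="duplicate"):
            om.read_expression_file(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("")
        assert om.read_expression_file(path) == []

    def test_negative_value_rejected(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("GDA\t-1.0\n")
        with pytest.raises(FileFormatError):
            om.read_expression_file(path)
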