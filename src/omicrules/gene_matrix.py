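"""Gene-level sample x feature matrices.

The central quantity on the methylation side is the *gene methylation
quantity*: for sample *i* and gene *j* with site-level beta values
``a_ij1 .. a_ijl``, the gene-level value is the plain sum

    b_ij = sum_h a_ijh

i.e. an intensity that grows with both the number of methylated CpG sites
annotated to the gene and their individual methylation levels.  Sites with
no gene annotation are excluded, as are sites whose beta is missing.

Matrices are stored as a :class:`GeneMatrix`: a float DataFrame (rows =
samples, columns = gene features, NaN = missing) plus one class label per
sample and an experiment tag.  On disk the format is CSV with a leading
``Sample_ID`` column, a trailing ``Class`` column and ``?`` for missing
entries.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tcga_io import (
    ExpressionRecord,
    FileFormatError,
    ManifestEntry,
    MethylationSiteRecord,
    class_from_barcode,
    parse_barcode,
    read_expression_file,
    read_methylation_file,
)

__all__ = [
    "EXPERIMENT_TAGS",
    "GeneMatrix",
    "aggregate_methylation",
    "aggregate_expression",
    "build_matrix",
    "write_matrix",
    "read_matrix",
    "matrices_from_manifest",
]

EXPERIMENT_TAGS = ("dnaMeth", "rnaSeq", "combined")

MISSING_TOKEN = "?"


@dataclass(eq=False)
class GeneMatrix:
    """Samples x gene-features table with a class label per sample.

    ``data`` holds float values with NaN for missing entries; ``classes``
    is index-aligned with ``data`` and holds one label per sample.
    """

    data: pd.DataFrame
    classes: pd.Series
    experiment_tag: str = "combined"

    def __post_init__(self) -> None:
        if self.experiment_tag not in EXPERIMENT_TAGS:
            raise ValueError(f"unknown experiment tag {self.experiment_tag!r}")
        if not self.data.index.is_unique:
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if not self.data.columns.is_unique:
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dup}")
        if not self.data.index.equals(self.classes.index):
            raise ValueError("class labels are not aligned with sample ids")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def m(self) -> int:
        return self.data.shape[1]

    def equals(self, other: "GeneMatrix") -> bool:
        return (
            self.experiment_tag == other.experiment_tag
            and self.classes.equals(other.classes)
            and self.data.equals(other.data)
        )


def aggregate_methylation(
    records: Iterable[MethylationSiteRecord],
) -> dict[str, float]:
    """Sum site-level beta values into per-gene methylation quantities.

    Records with a missing beta or an empty gene symbol contribute nothing.
    Composite annotations such as ``"A;B"`` credit the site's beta to every
    listed gene.  The result for a gene is in [0, number of its sites].
    """
    totals: dict[str, float] = {}
    for rec in records:
        if rec.beta is None or not rec.gene_symbol:
            continue
        for gene in rec.gene_symbol.split(";"):
            if not gene:
                continue
            totals[gene] = totals.get(gene, 0.0) + rec.beta
    return totals


def aggregate_expression(records: Iterable[ExpressionRecord]) -> dict[str, float]:
    """Map one sample's expression records to a gene -> value mapping."""
    out: dict[str, float] = {}
    for rec in records:
        if rec.gene_symbol in out:
            raise ValueError(f"duplicate gene symbol {rec.gene_symbol!r}")
        out[rec.gene_symbol] = rec.value
    return out


def build_matrix(
    per_sample: Mapping[str, Mapping[str, float]],
    labels: Mapping[str, str],
    experiment_tag: str = "combined",
    fill: str = "missing",
) -> GeneMatrix:
    """Assemble per-sample gene -> value mappings into one matrix.

    Features are the sorted union of genes over all samples; rows are sorted
    by sample id.  A gene unobserved in a sample is missing (``?``) by
    default — absence of measurement is not zero methylation — or 0.0 with
    ``fill="zero"``.
    """
    if fill not in ("missing", "zero"):
        raise ValueError(f"unknown fill policy {fill!r}")
    missing_labels = sorted(set(per_sample) - set(labels))
    if missing_labels:
        raise ValueError(f"samples without a class label: {missing_labels}")
    sample_ids = sorted(per_sample)
    features = sorted(set().union(*(per_sample[s].keys() for s in sample_ids)) if sample_ids else set())
    df = pd.DataFrame(
        [[per_sample[s].get(g, np.nan) for g in features] for s in sample_ids],
        index=sample_ids,
        columns=features,
        dtype=float,
    )
    if fill == "zero":
        df = df.fillna(0.0)
    classes = pd.Series([labels[s] for s in sample_ids], index=sample_ids, dtype=object)
    return GeneMatrix(df, classes, experiment_tag)


def _format_value(v: float) -> str:
    v = float(v)
    if math.isnan(v):
        return MISSING_TOKEN
    return repr(v)  # shortest round-tripping decimal form


def write_matrix(m: GeneMatrix, path: str | Path) -> None:
    """Write a matrix as CSV: Sample_ID, features..., Class; ``?`` = missing."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Sample_ID", *m.features, "Class"])
        values = m.values
        for i, sid in enumerate(m.sample_ids):
            writer.writerow(
                [sid, *(_format_value(v) for v in values[i]), m.classes.iloc[i]]
            )


def read_matrix(path: str | Path, experiment_tag: str = "combined") -> GeneMatrix:
    """Read a matrix CSV written by :func:`write_matrix`.

    Validates the header shape, row arity, and uniqueness of feature names
    and sample ids; ``read(write(m))`` reproduces ``m``.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FileFormatError(f"{path}: empty matrix file")
    header = rows[0]
    if len(header) < 2 or header[0] != "Sample_ID" or header[-1] != "Class":
        raise FileFormatError(
            f"{path}: header must start with 'Sample_ID' and end with 'Class'"
        )
    features = header[1:-1]
    if len(set(features)) != len(features):
        raise FileFormatError(f"{path}: duplicate feature names in header")
    sample_ids: list[str] = []
    labels: list[str] = []
    grid: list[list[float]] = []
    for rowno, row in enumerate(rows[1:], 2):
        if len(row) != len(header):
            raise FileFormatError(
                f"{path}:{rowno}: expected {len(header)} fields, got {len(row)}"
            )
        sample_ids.append(row[0])
        labels.append(row[-1])
        try:
            grid.append(
                [math.nan if tok == MISSING_TOKEN else float(tok) for tok in row[1:-1]]
            )
        except ValueError as exc:
            raise FileFormatError(f"{path}:{rowno}: {exc}") from exc
    df = pd.DataFrame(grid, index=sample_ids, columns=features, dtype=float)
    classes = pd.Series(labels, index=sample_ids, dtype=object)
    return GeneMatrix(df, classes, experiment_tag)


def matrices_from_manifest(
    entries: Sequence[ManifestEntry],
    base_dir: str | Path = ".",
    labels: Mapping[str, str] | None = None,
    meth_dialect=None,
    expr_dialect=None,
    fill: str = "missing",
) -> dict[str, GeneMatrix]:
    """Read per-sample files listed in a manifest and build per-experiment matrices.

    Class labels default to the barcode-derived condition; an explicit
    ``labels`` mapping (aliquot barcode -> label) overrides that.
    Returns a dict with keys among {"dnaMeth", "rnaSeq"}.
    """
    from .tcga_io import EXPRESSION_DIALECT, METHYLATION_DIALECT

    meth_dialect = meth_dialect or METHYLATION_DIALECT
    expr_dialect = expr_dialect or EXPRESSION_DIALECT
    base = Path(base_dir)
    per_exp: dict[str, dict[str, dict[str, float]]] = {}
    per_exp_labels: dict[str, dict[str, str]] = {}
    for entry in entries:
        if labels is not None and entry.barcode in labels:
            label = labels[entry.barcode]
        else:
            label = class_from_barcode(parse_barcode(entry.barcode))
        if entry.experiment == "dnaMeth":
            records = read_methylation_file(base / entry.path, meth_dialect)
            values = aggregate_methylation(records)
        else:
            records = read_expression_file(base / entry.path, expr_dialect)
            values = aggregate_expression(records)
        per_exp.setdefault(entry.experiment, {})[entry.barcode] = values
        per_exp_labels.setdefault(entry.experiment, {})[entry.barcode] = label
    return {
        exp: build_matrix(per_exp[exp], per_exp_labels[exp], exp, fill=fill)
        for exp in per_exp
    }
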