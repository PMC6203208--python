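"""Parsing of per-sample experiment files and TCGA aliquot barcodes.

A TCGA aliquot barcode is a dash-joined hierarchical identifier, e.g.
``TCGA-A7-A4SD-01A-11D-A268-05``: project, tissue source site, participant,
sample+vial, portion+analyte, plate, center.  The first two digits of the
sample field encode the tissue type: 01-09 are tumoral tissues, 10-19 are
matched normals, 20-29 are controls.  Only the first four fields identify
the physical tissue; the remainder describe the experiment performed on it,
which is why cross-experiment joins happen on the truncated (4-field) form.

Per-sample files come in two tab-separated dialects:

* methylation: one CpG site per line — chromosome, start, end (0-based
  half-open), strand, gene symbol, beta value in [0, 1];
* expression: one gene per line — gene symbol, normalized RSEM value.

Column positions, the separator and the tokens denoting a missing value are
configurable (:class:`FileDialect`), since upstream exporters differ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

__all__ = [
    "TUMORAL",
    "NORMAL",
    "BarcodeError",
    "UnsupportedSampleError",
    "FileFormatError",
    "SampleBarcode",
    "MethylationSiteRecord",
    "ExpressionRecord",
    "FileDialect",
    "METHYLATION_DIALECT",
    "EXPRESSION_DIALECT",
    "dialect_from_config",
    "parse_barcode",
    "truncate_barcode",
    "truncate_id",
    "class_from_barcode",
    "read_methylation_file",
    "read_expression_file",
    "ManifestEntry",
    "read_manifest",
    "write_manifest",
]

TUMORAL = "tumoral"
NORMAL = "normal"

_BARCODE_FIELDS = (
    "project",
    "tss",
    "participant",
    "sample_vial",
    "portion_analyte",
    "plate",
    "center",
)


class BarcodeError(ValueError):
    """A barcode string could not be parsed or violates barcode invariants."""


class UnsupportedSampleError(ValueError):
    """Sample-type code outside the tumoral/normal range (e.g. controls)."""


class FileFormatError(ValueError):
    """A per-sample file or matrix file violates its declared format."""


@dataclass(frozen=True)
class SampleBarcode:
    """Structured TCGA aliquot identifier.

    The first four fields are mandatory; the experiment-specific tail
    (portion/analyte, plate, center) may be absent, in which case the
    corresponding fields are empty strings.
    """

    project: str
    tss: str
    participant: str
    sample_vial: str
    portion_analyte: str = ""
    plate: str = ""
    center: str = ""

    def __post_init__(self) -> None:
        if len(self.sample_vial) < 2 or not self.sample_vial[:2].isdigit():
            raise BarcodeError(
                f"sample_vial field {self.sample_vial!r} must start with a "
                "2-digit sample-type code"
            )
        code = int(self.sample_vial[:2])
        if not 1 <= code <= 29:
            raise BarcodeError(
                f"sample-type code {code:02d} outside the supported range [01, 29]"
            )
        for name in ("project", "tss", "participant"):
            if not getattr(self, name):
                raise BarcodeError(f"barcode field {name!r} is empty")

    @property
    def sample_type_code(self) -> int:
        """Two-digit tissue-type code (01-09 tumoral, 10-19 normal)."""
        return int(self.sample_vial[:2])

    def __str__(self) -> str:
        parts = [getattr(self, name) for name in _BARCODE_FIELDS]
        return "-".join(p for p in parts if p)


def parse_barcode(aliquot: str) -> SampleBarcode:
    """Parse a dash-separated TCGA aliquot (or already-truncated) barcode.

    At least the four tissue-identifying fields must be present; trailing
    experiment fields are optional.
    """
    fields = aliquot.split("-")
    if len(fields) < 4:
        raise BarcodeError(
            f"barcode {aliquot!r} has {len(fields)} dash-separated fields; "
            "at least 4 are required (project-tss-participant-sample)"
        )
    if len(fields) > len(_BARCODE_FIELDS):
        raise BarcodeError(
            f"barcode {aliquot!r} has {len(fields)} fields; at most "
            f"{len(_BARCODE_FIELDS)} are supported"
        )
    return SampleBarcode(*fields)


def truncate_barcode(b: SampleBarcode) -> str:
    """Drop the experiment-specific fields, keeping project-tss-participant-sample.

    The result identifies the physical tissue sample and is the join key of
    the cross-experiment combination step.  Idempotent: truncating an
    already-truncated barcode is a no-op.
    """
    return "-".join((b.project, b.tss, b.participant, b.sample_vial))


def truncate_id(sample_id: str) -> str:
    """String-level convenience: parse then truncate."""
    return truncate_barcode(parse_barcode(sample_id))


def class_from_barcode(b: SampleBarcode) -> str:
    """Derive the condition label from the sample-type code.

    Codes 01-09 are tumoral tissues, 10-19 solid/blood-derived normals.
    Control codes (20-29) carry no case/control semantics here and raise.
    """
    code = b.sample_type_code
    if 1 <= code <= 9:
        return TUMORAL
    if 10 <= code <= 19:
        return NORMAL
    raise UnsupportedSampleError(
        f"sample-type code {code:02d} of {b} is a control code; "
        "only 01-19 map to tumoral/normal"
    )


@dataclass(frozen=True)
class MethylationSiteRecord:
    """One CpG-site measurement: genomic interval, gene annotation, beta value.

    ``beta`` is the methylated-allele intensity over the total intensity and
    therefore lies in [0, 1]; ``None`` marks a missing measurement.
    Coordinates follow the BED convention (0-based, half-open) but are used
    only as record identity, never arithmetically.
    """

    chrom: str
    start: int
    end: int
    strand: str
    gene_symbol: str
    beta: float | None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.beta is not None and not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta value {self.beta} outside [0, 1]")


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene-expression measurement (normalized RSEM value, >= 0)."""

    gene_symbol: str
    value: float

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("empty gene symbol in expression record")
        if self.value < 0:
            raise ValueError(f"negative expression value {self.value}")


@dataclass(frozen=True)
class FileDialect:
    """Column layout of a tab-separated per-sample file.

    ``columns`` maps logical field names to 0-based column indices; the file
    must have exactly ``max(columns.values()) + 1`` columns per line.
    ``missing_tokens`` apply to the value field (beta / expression) only.
    """

    columns: Mapping[str, int]
    separator: str = "\t"
    missing_tokens: frozenset[str] = frozenset({"NA", "na", ".", "?", ""})

    @property
    def width(self) -> int:
        return max(self.columns.values()) + 1


METHYLATION_DIALECT = FileDialect(
    columns={"chrom": 0, "start": 1, "end": 2, "strand": 3, "gene_symbol": 4, "beta": 5}
)
EXPRESSION_DIALECT = FileDialect(columns={"gene_symbol": 0, "value": 1})


def dialect_from_config(source: str | Path | Mapping) -> FileDialect:
    """Build a :class:`FileDialect` from a mapping or a YAML/JSON file.

    Recognized keys: ``columns`` (required), ``separator``, ``missing_tokens``.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        cfg = yaml.safe_load(text)  # YAML is a superset of JSON
    else:
        cfg = dict(source)
    if not isinstance(cfg, Mapping) or "columns" not in cfg:
        raise FileFormatError("dialect config must be a mapping with a 'columns' key")
    kwargs: dict = {"columns": dict(cfg["columns"])}
    if "separator" in cfg:
        kwargs["separator"] = cfg["separator"]
    if "missing_tokens" in cfg:
        kwargs["missing_tokens"] = frozenset(cfg["missing_tokens"])
    return FileDialect(**kwargs)


def _split_lines(path: str | Path, dialect: FileDialect) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split(dialect.separator)
            if len(fields) != dialect.width:
                raise FileFormatError(
                    f"{path}:{lineno}: expected {dialect.width} columns, "
                    f"got {len(fields)}"
                )
            yield lineno, fields


def read_methylation_file(
    path: str | Path, dialect: FileDialect = METHYLATION_DIALECT
) -> list[MethylationSiteRecord]:
    """Read one sample's CpG-site file into records.

    Lines whose beta field is a missing token are retained with
    ``beta=None`` (they are later skipped by the gene-level aggregation).
    """
    col = dialect.columns
    records: list[MethylationSiteRecord] = []
    for lineno, fields in _split_lines(path, dialect):
        beta_tok = fields[col["beta"]]
        try:
            beta = None if beta_tok in dialect.missing_tokens else float(beta_tok)
            rec = MethylationSiteRecord(
                chrom=fields[col["chrom"]],
                start=int(fields[col["start"]]),
                end=int(fields[col["end"]]),
                strand=fields[col["strand"]],
                gene_symbol=fields[col["gene_symbol"]],
                beta=beta,
            )
        except ValueError as exc:
            raise FileFormatError(f"{path}:{lineno}: {exc}") from exc
        records.append(rec)
    return records


def read_expression_file(
    path: str | Path, dialect: FileDialect = EXPRESSION_DIALECT
) -> list[ExpressionRecord]:
    """Read one sample's gene-expression file into records.

    A gene symbol appearing twice is ambiguous and raises; lines whose value
    field is a missing token are skipped (the gene counts as unobserved).
    """
    col = dialect.columns
    seen: set[str] = set()
    records: list[ExpressionRecord] = []
    for lineno, fields in _split_lines(path, dialect):
        gene = fields[col["gene_symbol"]]
        if gene in seen:
            raise FileFormatError(
                f"{path}:{lineno}: duplicate gene symbol {gene!r} "
                "(ambiguous expression value)"
            )
        seen.add(gene)
        tok = fields[col["value"]]
        if tok in dialect.missing_tokens:
            continue
        try:
            records.append(ExpressionRecord(gene_symbol=gene, value=float(tok)))
        except ValueError as exc:
            raise FileFormatError(f"{path}:{lineno}: {exc}") from exc
    return records


@dataclass(frozen=True)
class ManifestEntry:
    """One line of a cohort manifest: file path, aliquot barcode, experiment."""

    path: str
    barcode: str
    experiment: str  # "dnaMeth" or "rnaSeq"


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a 3-column tab-separated manifest (path, barcode, experiment)."""
    entries: list[ManifestEntry] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FileFormatError(
                    f"{path}:{lineno}: manifest lines need 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            if fields[2] not in ("dnaMeth", "rnaSeq"):
                raise FileFormatError(
                    f"{path}:{lineno}: unknown experiment {fields[2]!r}"
                )
            entries.append(ManifestEntry(*fields))
    return entries


def write_manifest(entries: Iterable[ManifestEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f"{e.path}\t{e.barcode}\t{e.experiment}\n")
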