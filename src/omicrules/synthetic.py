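"""Synthetic TCGA-like cohorts with planted class-discriminative genes.

The generator emulates the shapes the pipeline consumes without any
download: per-sample CpG-site methylation files (several sites per gene,
beta values in [0, 1]), per-sample expression files (nonnegative values),
syntactically valid aliquot barcodes whose sample-type code encodes the
condition (01 tumoral, 11 normal), and partially overlapping sample sets
between the two experiments.

Background site-level betas are Beta(2, 5) distributed (right-skewed, as
bulk methylation arrays typically are); background expression is
LogNormal(mu=2, sigma=1).  Planted methylation genes receive a
class-dependent location shift of ``effect_size`` at every site (truncated
to [0, 1]) in tumoral samples, so the gene-level beta sum inherits the
shift — this deliberately exercises the aggregation step.  Planted
expression genes receive an additive ``effect_size`` shift of the
log-expression (a multiplicative exp(effect_size) fold change) in tumoral
samples.  A truth record carries the planted gene lists and per-sample
latent classes for recovery checks.  Output is byte-identical for a fixed
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .combine import combine_matrices
from .gene_matrix import (
    GeneMatrix,
    aggregate_expression,
    aggregate_methylation,
    build_matrix,
)
from .tcga_io import (
    ExpressionRecord,
    ManifestEntry,
    MethylationSiteRecord,
    class_from_barcode,
    parse_barcode,
    truncate_id,
    write_manifest,
)

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "simulate_cohort",
    "matrices_from_cohort",
]

_B36 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_TSS_CODES = ("A1", "A7", "BH", "E2", "GI")


def _base36(i: int, width: int = 4) -> str:
    out = []
    for _ in range(width):
        out.append(_B36[i % 36])
        i //= 36
    return "".join(reversed(out))


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition knobs of the synthetic cohort.

    ``overlap`` gives the fractions of samples measured by (both
    experiments, methylation only, RNA-seq only); ``effect_size`` is the
    tumoral-vs-normal mean shift applied per CpG site on the beta scale and
    to the log-expression of planted genes.  ``planted_*_genes`` default to
    the first ten gene symbols of the universe.
    """

    n_tumoral: int = 100
    n_normal: int = 100
    n_genes: int = 500
    sites_per_gene: tuple[int, int] = (3, 8)
    planted_meth_genes: tuple[str, ...] | None = None
    planted_rna_genes: tuple[str, ...] | None = None
    effect_size: float = 0.5
    overlap: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumoral < 0 or self.n_normal < 0 or self.n_genes < 1:
            raise ValueError("cohort sizes must be nonnegative and n_genes >= 1")
        lo, hi = self.sites_per_gene
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid sites_per_gene range {self.sites_per_gene}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if abs(sum(self.overlap) - 1.0) > 1e-9 or min(self.overlap) < 0:
            raise ValueError(f"overlap fractions must be >= 0 and sum to 1, got {self.overlap}")
        universe = set(self.gene_universe)
        for name, planted in (
            ("planted_meth_genes", self.planted_meth_genes),
            ("planted_rna_genes", self.planted_rna_genes),
        ):
            if planted is not None and not set(planted) <= universe:
                missing = sorted(set(planted) - universe)
                raise ValueError(f"{name} outside the gene universe: {missing}")

    @property
    def gene_universe(self) -> list[str]:
        return [f"GENE{i:04d}" for i in range(self.n_genes)]

    @property
    def meth_planted(self) -> tuple[str, ...]:
        if self.planted_meth_genes is not None:
            return self.planted_meth_genes
        return tuple(self.gene_universe[: min(10, self.n_genes)])

    @property
    def rna_planted(self) -> tuple[str, ...]:
        if self.planted_rna_genes is not None:
            return self.planted_rna_genes
        return tuple(self.gene_universe[: min(10, self.n_genes)])


@dataclass
class SyntheticCohort:
    """Generated cohort: site/expression values plus the ground truth.

    ``meth_betas`` maps the methylation aliquot barcode to the per-site
    beta vector (ordered by gene, then site); ``rna_values`` maps the
    expression aliquot barcode to the per-gene value vector.
    """

    spec: CohortSpec
    genes: list[str]
    site_counts: np.ndarray  # sites per gene
    site_gene_index: np.ndarray  # gene index of every site
    meth_betas: dict[str, np.ndarray]
    rna_values: dict[str, np.ndarray]
    truth: dict

    def iter_methylation_records(self, barcode: str) -> Iterator[MethylationSiteRecord]:
        betas = self.meth_betas[barcode]
        offsets = np.concatenate([[0], np.cumsum(self.site_counts)])
        for g, gene in enumerate(self.genes):
            chrom = f"chr{(g % 22) + 1}"
            for s in range(int(self.site_counts[g])):
                start = 1_000 + g * 10_000 + s * 100
                yield MethylationSiteRecord(
                    chrom=chrom,
                    start=start,
                    end=start + 1,
                    strand="+",
                    gene_symbol=gene,
                    beta=float(betas[offsets[g] + s]),
                )

    def expression_records(self, barcode: str) -> list[ExpressionRecord]:
        values = self.rna_values[barcode]
        return [
            ExpressionRecord(gene_symbol=g, value=float(v))
            for g, v in zip(self.genes, values)
        ]

    def write(self, out_dir: str | Path) -> None:
        """Write per-sample files, a manifest and the truth record.

        Methylation files use the 6-column BED-like dialect, expression
        files the 2-column dialect; byte-identical across runs for a fixed
        spec seed.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        entries: list[ManifestEntry] = []
        for barcode in self.meth_betas:
            fname = f"{barcode}.meth.bed"
            with open(out / fname, "w") as fh:
                for rec in self.iter_methylation_records(barcode):
                    fh.write(
                        f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.strand}\t"
                        f"{rec.gene_symbol}\t{rec.beta!r}\n"
                    )
            entries.append(ManifestEntry(fname, barcode, "dnaMeth"))
        for barcode in self.rna_values:
            fname = f"{barcode}.rna.tsv"
            with open(out / fname, "w") as fh:
                for rec in self.expression_records(barcode):
                    fh.write(f"{rec.gene_symbol}\t{rec.value!r}\n")
            entries.append(ManifestEntry(fname, barcode, "rnaSeq"))
        write_manifest(entries, out / "manifest.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


def simulate_cohort(spec: CohortSpec | None = None) -> SyntheticCohort:
    """Draw a full synthetic cohort from a :class:`CohortSpec`."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_universe
    lo, hi = spec.sites_per_gene
    site_counts = rng.integers(lo, hi + 1, size=spec.n_genes)
    site_gene_index = np.repeat(np.arange(spec.n_genes), site_counts)
    total_sites = int(site_counts.sum())

    meth_planted_sites = np.isin(
        site_gene_index, [genes.index(g) for g in spec.meth_planted]
    )
    rna_planted_genes = np.isin(np.arange(spec.n_genes), [genes.index(g) for g in spec.rna_planted])

    n = spec.n_tumoral + spec.n_normal
    classes = ["tumoral"] * spec.n_tumoral + ["normal"] * spec.n_normal
    availability = rng.choice(3, size=n, p=spec.overlap)  # 0 both, 1 meth, 2 rna

    meth_betas: dict[str, np.ndarray] = {}
    rna_values: dict[str, np.ndarray] = {}
    truth_classes: dict[str, str] = {}
    for i in range(n):
        label = classes[i]
        tss = _TSS_CODES[int(rng.integers(len(_TSS_CODES)))]
        participant = _base36(i)
        sample_vial = "01A" if label == "tumoral" else "11A"
        stem = f"TCGA-{tss}-{participant}-{sample_vial}"
        plate = "A" + _base36(int(rng.integers(36**3)), width=3)
        truth_classes[stem] = label
        if availability[i] in (0, 1):
            betas = rng.beta(2.0, 5.0, size=total_sites)
            if label == "tumoral" and spec.effect_size > 0:
                betas[meth_planted_sites] = np.clip(
                    betas[meth_planted_sites] + spec.effect_size, 0.0, 1.0
                )
            meth_betas[f"{stem}-11D-{plate}-05"] = betas
        if availability[i] in (0, 2):
            log_expr = rng.normal(2.0, 1.0, size=spec.n_genes)
            if label == "tumoral" and spec.effect_size > 0:
                log_expr[rna_planted_genes] += spec.effect_size
            rna_values[f"{stem}-11R-{plate}-07"] = np.exp(log_expr)

    truth = {
        "planted_meth_genes": sorted(spec.meth_planted),
        "planted_rna_genes": sorted(spec.rna_planted),
        "classes": truth_classes,
        "effect_size": spec.effect_size,
        "seed": spec.seed,
    }
    return SyntheticCohort(
        spec=spec,
        genes=genes,
        site_counts=site_counts,
        site_gene_index=site_gene_index,
        meth_betas=meth_betas,
        rna_values=rna_values,
        truth=truth,
    )


def matrices_from_cohort(
    cohort: SyntheticCohort,
) -> tuple[GeneMatrix, GeneMatrix, GeneMatrix]:
    """Run the generated cohort through aggregation, matrix assembly and join.

    Class labels are derived from the generated barcodes (sample-type code
    01 vs 11), exactly as on real data.  Returns (methylation matrix,
    expression matrix, combined matrix).
    """
    meth_values = {
        bc: aggregate_methylation(cohort.iter_methylation_records(bc))
        for bc in cohort.meth_betas
    }
    rna_values = {
        bc: aggregate_expression(cohort.expression_records(bc))
        for bc in cohort.rna_values
    }
    labels = {
        bc: class_from_barcode(parse_barcode(bc))
        for bc in (*meth_values, *rna_values)
    }
    meth = build_matrix(meth_values, labels, "dnaMeth")
    rna = build_matrix(rna_values, labels, "rnaSeq")
    return meth, rna, combine_matrices(meth, rna)
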