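"""Cross-experiment combination of gene matrices.

The combined matrix is a full outer join of the methylation and expression
matrices on the truncated sample barcode (the first four barcode fields):
rows present in both experiments get both value blocks, rows present in one
get ``?`` (missing) across the entire other block.  Feature namespaces are
kept disjoint by suffixing — ``GDA`` measured by methylation becomes
``GDA_dnaMeth``, by RNA-seq ``GDA_rnaSeq`` — so the combined width is
exactly the sum of the two input widths even when gene symbols overlap.
No value is altered by the join.
"""

from __future__ import annotations

import pandas as pd

from .gene_matrix import GeneMatrix
from .tcga_io import truncate_id

__all__ = [
    "DEFAULT_SUFFIXES",
    "AmbiguousSampleError",
    "ClassConflictError",
    "combine_matrices",
    "drop_incomplete_samples",
]

#: canonical feature-name suffixes for the two experiments
DEFAULT_SUFFIXES = ("_dnaMeth", "_rnaSeq")


class AmbiguousSampleError(ValueError):
    """Two aliquots of the same physical sample within one experiment."""


class ClassConflictError(ValueError):
    """The same truncated sample id carries different class labels."""


def _truncated_frame(m: GeneMatrix, suffix: str) -> tuple[pd.DataFrame, pd.Series]:
    truncated = [truncate_id(s) for s in m.sample_ids]
    dup = sorted({t for t in truncated if truncated.count(t) > 1})
    if dup:
        raise AmbiguousSampleError(
            f"multiple {m.experiment_tag} aliquots map to the same sample(s): {dup}"
        )
    df = m.data.copy()
    df.index = truncated
    df.columns = [f"{c}{suffix}" for c in m.features]
    df = df[sorted(df.columns)]
    classes = pd.Series(list(m.classes), index=truncated, dtype=object)
    return df, classes


def combine_matrices(
    meth: GeneMatrix,
    rna: GeneMatrix,
    suffixes: tuple[str, str] = DEFAULT_SUFFIXES,
) -> GeneMatrix:
    """Full outer join of a methylation and an expression matrix.

    Sample ids may be full aliquot barcodes or already-truncated ids; the
    join key is always the truncated form.  The output feature list is all
    (suffixed) methylation features followed by all (suffixed) expression
    features, each block in lexicographic order; rows are sorted by the
    truncated id.  Conflicting class labels for a shared sample raise
    :class:`ClassConflictError`.
    """
    if meth.experiment_tag != "dnaMeth":
        raise ValueError(f"first input must be a dnaMeth matrix, got {meth.experiment_tag!r}")
    if rna.experiment_tag != "rnaSeq":
        raise ValueError(f"second input must be an rnaSeq matrix, got {rna.experiment_tag!r}")
    md, mc = _truncated_frame(meth, suffixes[0])
    rd, rc = _truncated_frame(rna, suffixes[1])
    shared = mc.index.intersection(rc.index)
    conflicts = [s for s in shared if mc[s] != rc[s]]
    if conflicts:
        raise ClassConflictError(
            f"conflicting class labels for sample(s): {sorted(conflicts)}"
        )
    index = sorted(set(md.index) | set(rd.index))
    data = pd.concat([md.reindex(index), rd.reindex(index)], axis=1)
    classes = mc.reindex(index).astype(object)
    classes = classes.where(classes.notna(), rc.reindex(index))
    return GeneMatrix(data, classes, "combined")


def drop_incomplete_samples(
    combined: GeneMatrix, suffixes: tuple[str, str] = DEFAULT_SUFFIXES
) -> GeneMatrix:
    """Keep only samples measured by both experiments (complete cases).

    A sample is complete when each experiment block contains at least one
    non-missing value for it.
    """
    blocks = [
        [c for c in combined.features if c.endswith(sfx)] for sfx in suffixes
    ]
    keep = pd.Series(True, index=combined.data.index)
    for cols in blocks:
        keep &= combined.data[cols].notna().any(axis=1) if cols else False
    data = combined.data.loc[keep]
    return GeneMatrix(data, combined.classes.loc[keep], "combined")
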