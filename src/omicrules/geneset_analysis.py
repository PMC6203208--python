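"""Gene-set extraction from rule models and Venn-region intersection counts.

Combined-matrix feature names carry an experiment suffix (``GDA_dnaMeth``,
``GDA_rnaSeq``; the abbreviated ``_dMeth`` / ``_rna`` renderings are also
recognized).  Stripping the suffix recovers the bare gene symbol together
with the experiment the measurement came from, which is what the
cross-tumor and cross-experiment set comparisons operate on.  Gene
identity is the bare symbol string, case-sensitive; no alias resolution.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping

from .rule_induction import RuleModel

__all__ = [
    "SUFFIX_EXPERIMENTS",
    "SuffixError",
    "genes_from_features",
    "genes_from_model",
    "venn_regions",
    "venn_counts",
]

#: recognized feature-name suffixes, longest first, mapped to the experiment
SUFFIX_EXPERIMENTS = (
    ("_dnaMeth", "dnaMeth"),
    ("_rnaSeq", "rnaSeq"),
    ("_dMeth", "dnaMeth"),
    ("_rna", "rnaSeq"),
)


class SuffixError(ValueError):
    """A combined-matrix feature name lacks a recognized experiment suffix."""


def _split_feature(feature: str) -> tuple[str, str]:
    for suffix, experiment in SUFFIX_EXPERIMENTS:
        if feature.endswith(suffix) and len(feature) > len(suffix):
            return feature[: -len(suffix)], experiment
    raise SuffixError(
        f"feature {feature!r} carries no recognized experiment suffix "
        f"({', '.join(s for s, _ in SUFFIX_EXPERIMENTS)})"
    )


def genes_from_features(
    features: Iterable[str], experiment: str | None = None
) -> set[tuple[str, str]]:
    """Map feature names to (gene_symbol, experiment) pairs.

    With ``experiment`` given (single-experiment matrix), names are taken
    as bare gene symbols; otherwise each name must carry a recognized
    suffix.  Duplicates collapse.
    """
    if experiment is not None:
        return {(f, experiment) for f in features}
    return {_split_feature(f) for f in features}


def genes_from_model(
    model: RuleModel | Iterable[str], experiment: str | None = None
) -> set[tuple[str, str]]:
    """Extract the (gene, experiment) set used by a rule model's conditions."""
    features = model.features if isinstance(model, RuleModel) else model
    return genes_from_features(features, experiment)


def venn_regions(sets: Mapping[str, Iterable]) -> dict[tuple[str, ...], set]:
    """Exclusive membership regions of 2 or 3 named sets.

    The key ``(A,)`` holds elements in A only, ``(A, B)`` elements in
    exactly A and B, and so on; keys are sorted name tuples and every
    element of the union lands in exactly one region.
    """
    if len(sets) not in (2, 3):
        raise ValueError(f"2 or 3 named sets supported, got {len(sets)}")
    materialized = {name: set(values) for name, values in sets.items()}
    names = sorted(materialized)
    regions: dict[tuple[str, ...], set] = {}
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            inside = set.intersection(*(materialized[n] for n in combo))
            outside = set.union(
                *(materialized[n] for n in names if n not in combo), set()
            )
            regions[combo] = inside - outside
    return regions


def venn_counts(sets: Mapping[str, Iterable]) -> dict[tuple[str, ...], int]:
    """Element counts of each exclusive Venn region; they sum to |union|."""
    return {region: len(members) for region, members in venn_regions(sets).items()}
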