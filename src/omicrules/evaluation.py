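"""Classification metrics, cross-validation, grid search and permutation tests.

The figure of merit throughout is the F-measure, F = 2PR/(P+R) with
P = TP/(TP+FP) and R = TP/(TP+FN); degenerate denominators yield 0.  Model
quality is reported as the macro average of the per-class F over the two
classes, averaged over stratified k-fold cross-validation folds (the
support-weighted average is reported alongside, since published summaries
use either convention).

Permutation validation refits and cross-validates the learner on uniformly
shuffled class labels: the permutation destroys any genuine association
between features and condition, so a sound pipeline must fall back to
chance-level F there, and a permuted score rivalling the true-label score
is the signature of overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .gene_matrix import GeneMatrix

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "precision",
    "recall",
    "f_measure",
    "CVResult",
    "cross_validate",
    "tune_parameters",
    "PermutationResult",
    "permutation_validation",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class confusion counts; tp+fp+tn+fn equals the evaluated n."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(y_true, y_pred, cls) -> ConfusionCounts:
    yt = np.asarray(y_true, dtype=object)
    yp = np.asarray(y_pred, dtype=object)
    return ConfusionCounts(
        tp=int(np.sum((yt == cls) & (yp == cls))),
        fp=int(np.sum((yt != cls) & (yp == cls))),
        tn=int(np.sum((yt != cls) & (yp != cls))),
        fn=int(np.sum((yt == cls) & (yp != cls))),
    )


def precision(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0


def recall(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0


def f_measure(c: ConfusionCounts) -> float:
    p, r = precision(c), recall(c)
    return 2 * p * r / (p + r) if p + r else 0.0


def _derive_seed(seed: int, k: int) -> int:
    return (seed * 100_003 + k + 1) % (2**31 - 1)


@dataclass
class CVResult:
    """Per-fold and aggregate cross-validation scores."""

    classes: list[str]
    per_class_f: list[dict[str, float]]  # one dict per fold
    macro_f: list[float]  # per fold
    weighted_f: list[float]  # per fold, support-weighted
    mean_macro_f: float
    mean_weighted_f: float
    mean_per_class_f: dict[str, float]


def cross_validate(m: GeneMatrix, learner, k: int = 10, seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validation of a learner on a gene matrix.

    Each fold trains on k-1 parts and scores on the held-out part; fold
    assignment and the per-fold learner seeds are derived from ``seed``, so
    the whole procedure is deterministic.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = m.classes
    classes = sorted(pd.unique(y.to_numpy(dtype=object)))
    counts = y.value_counts()
    if int(counts.min()) < k:
        small = counts.idxmin()
        raise ValueError(
            f"class {small!r} has {int(counts.min())} members, fewer than "
            f"k={k} folds; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_class_f: list[dict[str, float]] = []
    macro_f: list[float] = []
    weighted_f: list[float] = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(m.n), y.to_numpy(dtype=object))):
        model = learner.fit(m.data.iloc[tr], y.iloc[tr], seed=_derive_seed(seed, fold))
        pred = model.predict_frame(m.data.iloc[te])
        truth = y.iloc[te].to_numpy(dtype=object)
        fold_f = {cls: f_measure(confusion_counts(truth, pred, cls)) for cls in classes}
        support = {cls: int(np.sum(truth == cls)) for cls in classes}
        per_class_f.append(fold_f)
        macro_f.append(float(np.mean(list(fold_f.values()))))
        weighted_f.append(
            float(sum(fold_f[c] * support[c] for c in classes) / len(te))
        )
    mean_per_class = {
        cls: float(np.mean([f[cls] for f in per_class_f])) for cls in classes
    }
    return CVResult(
        classes=list(classes),
        per_class_f=per_class_f,
        macro_f=macro_f,
        weighted_f=weighted_f,
        mean_macro_f=float(np.mean(macro_f)),
        mean_weighted_f=float(np.mean(weighted_f)),
        mean_per_class_f=mean_per_class,
    )


def tune_parameters(
    m: GeneMatrix,
    learner,
    grid: Sequence[Mapping],
    k: int = 10,
    seed: int = 0,
) -> tuple[Mapping, float, list[float]]:
    """Exhaustive grid search maximizing mean CV macro-F.

    ``grid`` is a sequence of parameter mappings applied to the learner via
    ``with_params``; ties keep the earlier grid entry.  Returns the winning
    parameter set, its score, and all scores in grid order.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    scores: list[float] = []
    best_i = 0
    for i, params in enumerate(grid):
        res = cross_validate(m, learner.with_params(**params), k=k, seed=seed)
        scores.append(res.mean_macro_f)
        if scores[i] > scores[best_i]:
            best_i = i
    return grid[best_i], scores[best_i], scores


@dataclass
class PermutationResult:
    """Mean CV macro-F of each label-permutation replicate and their average."""

    replicates: list[float]
    grand_mean: float  # NaN when there are no replicates


def permutation_validation(
    m: GeneMatrix,
    learner,
    n_perm: int,
    k: int = 10,
    seed: int = 0,
) -> PermutationResult:
    """Re-run cross-validation on randomly permuted class labels.

    Each replicate shuffles the labels across samples (a pure permutation,
    preserving class frequencies), then cross-validates the learner on the
    relabeled matrix.  All randomness derives from ``seed``.
    """
    replicates: list[float] = []
    for rep in range(n_perm):
        rng = np.random.default_rng([seed, rep])
        perm = rng.permutation(m.n)
        shuffled = pd.Series(
            m.classes.to_numpy(dtype=object)[perm], index=m.data.index, dtype=object
        )
        pm = GeneMatrix(m.data, shuffled, m.experiment_tag)
        res = cross_validate(pm, learner, k=k, seed=_derive_seed(seed, rep))
        replicates.append(res.mean_macro_f)
    grand = float(np.mean(replicates)) if replicates else float("nan")
    return PermutationResult(replicates=replicates, grand_mean=grand)
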