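"""Sequential-covering induction of ordered threshold-rule models.

The learner produces models of the form used throughout rule-based
case/control genomics, e.g.::

    (MAP3K11_dnaMeth <= 12.3) and (PIP5KL1_dnaMeth >= 2.1) => class=normal
    => class=tumoral

i.e. an ordered list of conjunctive rules for the minority class followed
by a default (majority-class) prediction.  Prediction is first-match; a
condition evaluated on a missing value is false, so a rule never covers a
sample that lacks one of its features.

The induction scheme is IREP-style (incremental reduced-error pruning):

* the active training examples are split 2:1 (stratified, seeded) into a
  grow and a prune part;
* a rule is grown greedily, adding at each step the threshold condition
  with the largest FOIL information gain; candidate thresholds are the
  midpoints of consecutive distinct sorted feature values;
* the grown rule is pruned back to the condition prefix maximizing
  (p - n) / (p + n) on the prune part;
* the rule is kept if its prune-part precision is at least 0.5 and it
  covers at least ``min_coverage`` positives; covered examples are removed
  and the loop repeats until no positives remain.

On very small inputs (fewer than ``min_prune_n`` active examples, or a
class with fewer than two members) holding out a prune part would be pure
noise, so rules are grown on the full active set without reduced-error
pruning.  A global optimization pass in the spirit of RIPPER's is provided
as repeat-and-keep-best: the procedure is run ``optimization_runs + 1``
times with distinct derived seeds and the model with the highest training
macro F-measure is returned.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Rule",
    "RuleModel",
    "RipperParams",
    "RipperLearner",
    "learn_ruleset",
]

_OPS = ("<=", ">=")


@dataclass(frozen=True)
class Condition:
    """A single threshold literal, ``feature <= t`` or ``feature >= t``."""

    feature: str
    op: str
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown operator {self.op!r}")

    def holds(self, value) -> bool:
        """Evaluate on a scalar; missing (None/NaN) never satisfies."""
        if value is None:
            return False
        v = float(value)
        if math.isnan(v):
            return False
        return v <= self.threshold if self.op == "<=" else v >= self.threshold

    def holds_array(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return v <= self.threshold if self.op == "<=" else v >= self.threshold

    def __str__(self) -> str:
        return f"({self.feature} {self.op} {self.threshold:g})"


@dataclass(frozen=True)
class Rule:
    """A conjunction of conditions predicting ``target_class``."""

    conditions: tuple[Condition, ...]
    target_class: str

    def covers(self, sample: Mapping[str, float]) -> bool:
        """True iff every condition holds; the empty conjunction covers all."""
        return all(c.holds(sample.get(c.feature)) for c in self.conditions)

    def covers_frame(self, df: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(df), dtype=bool)
        for c in self.conditions:
            mask &= c.holds_array(df[c.feature].to_numpy(dtype=float))
        return mask

    @property
    def features(self) -> frozenset[str]:
        return frozenset(c.feature for c in self.conditions)

    def __str__(self) -> str:
        body = " and ".join(str(c) for c in self.conditions)
        return f"{body} => class={self.target_class}"


@dataclass
class RuleModel:
    """Ordered rules plus a default class; prediction is first-match."""

    rules: list[Rule]
    default_class: str
    train_f_measure: float = math.nan

    def predict(self, sample: Mapping[str, float]) -> str:
        for rule in self.rules:
            if rule.covers(sample):
                return rule.target_class
        return self.default_class

    def predict_frame(self, df: pd.DataFrame) -> np.ndarray:
        out = np.full(len(df), self.default_class, dtype=object)
        assigned = np.zeros(len(df), dtype=bool)
        for rule in self.rules:
            hit = rule.covers_frame(df) & ~assigned
            out[hit] = rule.target_class
            assigned |= hit
        return out

    @property
    def features(self) -> frozenset[str]:
        """Union of features appearing in any rule."""
        return frozenset().union(*(r.features for r in self.rules)) if self.rules else frozenset()

    def to_dict(self) -> dict:
        return {
            "rules": [
                {
                    "conditions": [
                        {"feature": c.feature, "op": c.op, "threshold": c.threshold}
                        for c in r.conditions
                    ],
                    "class": r.target_class,
                }
                for r in self.rules
            ],
            "default": self.default_class,
            "train_f": None if math.isnan(self.train_f_measure) else self.train_f_measure,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleModel":
        rules = [
            Rule(
                tuple(
                    Condition(c["feature"], c["op"], c["threshold"])
                    for c in r["conditions"]
                ),
                r["class"],
            )
            for r in d["rules"]
        ]
        train_f = d.get("train_f")
        return cls(rules, d["default"], math.nan if train_f is None else train_f)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def render(self) -> str:
        """Human-readable listing in the ``(F <= t) and ... => class=c`` style."""
        lines = [str(r) for r in self.rules]
        lines.append(f"=> class={self.default_class}")
        lines.append(f"Number of Rules: {len(self.rules) + 1}")
        return "\n".join(lines)


@dataclass(frozen=True)
class RipperParams:
    """Tunable knobs of the rule learner.

    grow_prune_split:
        fraction of the active examples used for growing; ``None`` derives
        it as ``1 - 1/prune_folds`` (the Weka-style -F parameter).
    optimization_runs:
        extra repeat-and-keep-best passes (0 disables them).
    min_coverage:
        minimum number of training positives a retained rule must cover.
    min_prune_n:
        below this many active examples, reduced-error pruning is skipped.
    """

    grow_prune_split: float | None = None
    prune_folds: int = 3
    optimization_runs: int = 2
    seed: int = 0
    min_coverage: int = 1
    min_prune_n: int = 16
    max_conditions: int = 15
    max_rules: int = 50

    @property
    def grow_fraction(self) -> float:
        if self.grow_prune_split is not None:
            return self.grow_prune_split
        return 1.0 - 1.0 / self.prune_folds


def _macro_f(y_true: np.ndarray, y_pred: np.ndarray, classes: Sequence[str]) -> float:
    fs = []
    for cls in classes:
        tp = np.sum((y_true == cls) & (y_pred == cls))
        fp = np.sum((y_true != cls) & (y_pred == cls))
        fn = np.sum((y_true == cls) & (y_pred != cls))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        fs.append(2 * p * r / (p + r) if p + r else 0.0)
    return float(np.mean(fs))


def _coverage_mask(conds: Sequence[Condition], X: np.ndarray, col_index: Mapping[str, int]) -> np.ndarray:
    mask = np.ones(X.shape[0], dtype=bool)
    for c in conds:
        mask &= c.holds_array(X[:, col_index[c.feature]])
    return mask


def _best_condition(
    Xg: np.ndarray,
    yg: np.ndarray,
    covered: np.ndarray,
    feature_names: Sequence[str],
):
    """Vectorized scan for the FOIL-gain-maximizing threshold condition.

    Candidate thresholds are midpoints of consecutive distinct sorted values
    of each feature among the currently covered grow examples.  Ties are
    broken by feature order, then ``<=`` before ``>=``, then the smaller
    midpoint.  Returns (condition, gain) or None if no candidate has
    positive gain.
    """
    sub = Xg[covered]
    ysub = yg[covered]
    nc = sub.shape[0]
    if nc < 2:
        return None
    p0 = int(ysub.sum())
    n0 = nc - p0
    if p0 == 0:
        return None
    base = math.log2(p0 / (p0 + n0))

    order = np.argsort(sub, axis=0, kind="stable")  # NaN sorted last
    Xs = np.take_along_axis(sub, order, axis=0)
    ys = ysub[order]
    finite = ~np.isnan(Xs)
    fcount = finite.sum(axis=0)  # finite values per column
    cpos = np.cumsum(ys & finite, axis=0).astype(float)
    totpos = cpos[-1]

    cnt = np.arange(1, nc, dtype=float)[:, None]  # samples at or below boundary k
    with np.errstate(invalid="ignore"):
        mids = (Xs[:-1] + Xs[1:]) / 2.0
        valid = (cnt < fcount[None, :]) & (Xs[1:] > Xs[:-1])
    p_le = cpos[:-1]
    n_le = cnt - p_le
    p_ge = totpos[None, :] - cpos[:-1]
    n_ge = (fcount[None, :] - cnt) - p_ge

    def gain(p: np.ndarray, n: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            g = p * (np.log2(p / (p + n)) - base)
        g = np.where((p >= 1) & valid, g, -np.inf)
        return g

    g_le = gain(p_le, n_le)
    g_ge = gain(p_ge, n_ge)
    best = max(g_le.max(initial=-np.inf), g_ge.max(initial=-np.inf))
    if not np.isfinite(best) or best <= 0.0:
        return None

    candidates = []  # (feature_idx, op_rank, midpoint)
    for op_rank, g in enumerate((g_le, g_ge)):
        for k, j in zip(*np.nonzero(g == best)):
            candidates.append((int(j), op_rank, float(mids[k, j])))
    j, op_rank, mid = min(candidates)
    return Condition(feature_names[j], _OPS[op_rank], mid), best


def _grow_rule(
    Xg: np.ndarray,
    yg: np.ndarray,
    feature_names: Sequence[str],
    params: RipperParams,
) -> list[Condition]:
    covered = np.ones(Xg.shape[0], dtype=bool)
    conds: list[Condition] = []
    col_index = {f: i for i, f in enumerate(feature_names)}
    while len(conds) < params.max_conditions:
        n_neg = int((~yg[covered]).sum())
        if n_neg == 0:
            break
        found = _best_condition(Xg, yg, covered, feature_names)
        if found is None:
            break
        cond, _ = found
        conds.append(cond)
        covered &= cond.holds_array(Xg[:, col_index[cond.feature]])
    return conds


def _prune_rule(
    conds: list[Condition],
    Xp: np.ndarray,
    yp: np.ndarray,
    col_index: Mapping[str, int],
) -> list[Condition]:
    """Keep the condition prefix maximizing (p - n)/(p + n) on the prune set.

    Ties prefer the shorter prefix (more aggressive pruning); a prefix
    covering nothing on the prune set scores -1.
    """
    best_k, best_v = 1, -math.inf
    cov = np.ones(Xp.shape[0], dtype=bool)
    for k, cond in enumerate(conds, 1):
        cov &= cond.holds_array(Xp[:, col_index[cond.feature]])
        p = int(yp[cov].sum())
        n = int(cov.sum()) - p
        v = (p - n) / (p + n) if p + n else -1.0
        if v > best_v:
            best_k, best_v = k, v
    return conds[:best_k]


def _stratified_split(
    idx: np.ndarray, y01: np.ndarray, grow_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    grow_parts, prune_parts = [], []
    for cls_mask in (y01[idx], ~y01[idx]):
        members = idx[cls_mask]
        perm = members[rng.permutation(members.size)]
        n_grow = int(round(grow_fraction * members.size))
        n_grow = min(max(n_grow, 1), members.size - 1)
        grow_parts.append(perm[:n_grow])
        prune_parts.append(perm[n_grow:])
    return np.concatenate(grow_parts), np.concatenate(prune_parts)


def _irep(
    X: np.ndarray,
    y01: np.ndarray,
    target: str,
    feature_names: Sequence[str],
    params: RipperParams,
    seed_material,
) -> list[Rule]:
    rng = np.random.default_rng(seed_material)
    col_index = {f: i for i, f in enumerate(feature_names)}
    active = np.ones(X.shape[0], dtype=bool)
    rules: list[Rule] = []
    while len(rules) < params.max_rules:
        idx = np.flatnonzero(active)
        n_pos = int(y01[idx].sum())
        n_neg = idx.size - n_pos
        if n_pos == 0:
            break
        use_prune = idx.size >= params.min_prune_n and n_pos >= 2 and n_neg >= 2
        if use_prune:
            grow_idx, prune_idx = _stratified_split(idx, y01, params.grow_fraction, rng)
        else:
            grow_idx, prune_idx = idx, None
        conds = _grow_rule(X[grow_idx], y01[grow_idx], feature_names, params)
        if not conds:
            break
        if prune_idx is not None:
            conds = _prune_rule(conds, X[prune_idx], y01[prune_idx], col_index)
            eval_idx = prune_idx
        else:
            eval_idx = grow_idx
        cov_eval = _coverage_mask(conds, X[eval_idx], col_index)
        p = int(y01[eval_idx][cov_eval].sum())
        n = int(cov_eval.sum()) - p
        if p == 0 or p / (p + n) < 0.5:
            break
        cov_full = _coverage_mask(conds, X, col_index)
        if int(y01[cov_full].sum()) < params.min_coverage:
            break
        rules.append(Rule(tuple(conds), target))
        active &= ~cov_full
    return rules


def learn_ruleset(
    matrix,
    params: RipperParams | None = None,
) -> RuleModel:
    """Learn an ordered rule model from a binary-class gene matrix.

    ``matrix`` is a :class:`~omicrules.gene_matrix.GeneMatrix` or a
    ``(DataFrame, Series)`` pair.  Rules target the minority class (ties go
    to the lexicographically first class); the default class is the
    majority.  Deterministic for fixed input and ``params.seed``.
    """
    params = params or RipperParams()
    if hasattr(matrix, "data"):
        df, y = matrix.data, matrix.classes
    else:
        df, y = matrix
    labels = y.to_numpy(dtype=object)
    classes = sorted(pd.unique(labels))
    if len(classes) > 2:
        raise ValueError(f"binary classification only; got classes {classes}")
    if len(classes) == 1:
        return RuleModel([], classes[0], 1.0)

    counts = {c: int((labels == c).sum()) for c in classes}
    if counts[classes[0]] <= counts[classes[1]]:
        target, default = classes[0], classes[1]
    else:
        target, default = classes[1], classes[0]
    X = df.to_numpy(dtype=float)
    y01 = labels == target
    feature_names = list(df.columns)

    best_model: RuleModel | None = None
    for run in range(params.optimization_runs + 1):
        rules = _irep(X, y01, target, feature_names, params, [params.seed, run])
        pred = RuleModel(rules, default).predict_frame(df)
        score = _macro_f(labels, pred, classes)
        if best_model is None or score > best_model.train_f_measure:
            best_model = RuleModel(rules, default, score)
    assert best_model is not None
    return best_model


class RipperLearner:
    """Thin pluggable-learner wrapper around :func:`learn_ruleset`.

    Any object with ``fit(X, y, seed) -> model`` (the model exposing
    ``predict_frame``) and ``with_params(**kw)`` satisfies the learner
    contract used by the evaluation and multi-model extraction layers, so a
    third-party rule learner can be substituted.
    """

    def __init__(self, params: RipperParams | None = None, **overrides):
        params = params or RipperParams()
        if overrides:
            params = replace(params, **overrides)
        self.params = params

    def with_params(self, **kw) -> "RipperLearner":
        return RipperLearner(replace(self.params, **kw))

    def fit(self, X: pd.DataFrame, y: pd.Series, seed: int | None = None) -> RuleModel:
        params = self.params if seed is None else replace(self.params, seed=seed)
        return learn_ruleset((X, y), params)

    def __repr__(self) -> str:
        return f"RipperLearner({self.params})"
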