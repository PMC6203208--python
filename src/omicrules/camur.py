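"""Iterative extraction of multiple alternative rule-based models.

A single rule learner returns one parsimonious model and hides every
equally predictive alternative.  The extractor here recovers them by
repeated feature elimination: learn a model, record the features its rules
use, remove (some of) them from the matrix, learn again.  Two modes:

* **standard** — features of every archived model are removed permanently;
  the loop stops as soon as the cross-validated F-measure of the freshly
  learned model drops below the quality threshold (or a cap is hit).
  Archived models therefore use pairwise-disjoint rule features.
* **loose** — elimination is temporary: candidate elimination subsets of
  the pool of previously used features are queued and each iteration
  trains with one subset removed, archiving the model when it clears the
  threshold and its rule-feature set is new.  After archiving a novel
  model learned with elimination set E and rule features R, the subset
  E ∪ R is enqueued first (the chain that keeps uncovering the next
  alternative), then the singletons of R; once the queue drains, remaining
  pool subsets are enumerated size-ascending, lexicographically.  The loop
  stops on queue exhaustion or a cap.

Per-iteration model quality is the mean macro F-measure over stratified
k-fold cross-validation on the reduced matrix; the archived model itself
is refit on all samples.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import time
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .evaluation import cross_validate
from .gene_matrix import GeneMatrix
from .rule_induction import RipperLearner, RuleModel

__all__ = [
    "CamurConfig",
    "ArchivedModel",
    "CamurRun",
    "run_camur",
    "analyze_run",
]


@dataclass(frozen=True)
class CamurConfig:
    """Configuration of the iterative extraction.

    Defaults mirror the reference setup: minimum F-measure 0.8, at most 100
    iterations, a 30-day wall-clock cap, 10-fold internal cross-validation.
    """

    mode: str = "loose"
    f_threshold: float = 0.8
    max_iterations: int = 100
    max_time_s: float = 30 * 86_400.0
    seed: int = 0
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if self.mode not in ("standard", "loose"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.f_threshold <= 1.0:
            raise ValueError(f"f_threshold must be in (0, 1], got {self.f_threshold}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


@dataclass
class ArchivedModel:
    """One archived model with the elimination set that produced it."""

    model: RuleModel
    eliminated_features: frozenset[str]
    cv_f_measure: float


@dataclass
class CamurRun:
    """Archive of all models plus bookkeeping of the iterative procedure."""

    models: list[ArchivedModel]
    iterations_executed: int
    stop_reason: str  # below_threshold | max_iterations | time_limit | exhausted

    def to_dict(self) -> dict:
        return {
            "models": [
                {
                    "model": a.model.to_dict(),
                    "eliminated_features": sorted(a.eliminated_features),
                    "cv_f_measure": a.cv_f_measure,
                }
                for a in self.models
            ],
            "iterations_executed": self.iterations_executed,
            "stop_reason": self.stop_reason,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CamurRun":
        return cls(
            models=[
                ArchivedModel(
                    model=RuleModel.from_dict(a["model"]),
                    eliminated_features=frozenset(a["eliminated_features"]),
                    cv_f_measure=a["cv_f_measure"],
                )
                for a in d["models"]
            ],
            iterations_executed=d["iterations_executed"],
            stop_reason=d["stop_reason"],
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _derive_seed(seed: int, k: int) -> int:
    return (seed * 99_991 + 7 * k + 1) % (2**31 - 1)


def run_camur(m: GeneMatrix, cfg: CamurConfig | None = None, learner=None) -> CamurRun:
    """Extract multiple alternative rule models by iterative feature elimination."""
    cfg = cfg or CamurConfig()
    n_classes = m.classes.nunique()
    if n_classes != 2:
        raise ValueError(f"binary-class matrix required, found {n_classes} class(es)")
    learner = learner or RipperLearner(seed=cfg.seed)
    start = time.monotonic()
    all_features = list(m.data.columns)

    archived: list[ArchivedModel] = []
    seen_rule_sets: set[frozenset[str]] = set()
    iterations = 0

    def out_of_budget() -> str | None:
        if iterations >= cfg.max_iterations:
            return "max_iterations"
        if time.monotonic() - start > cfg.max_time_s:
            return "time_limit"
        return None

    def train(eliminated: frozenset[str]) -> tuple[RuleModel, float]:
        cols = [f for f in all_features if f not in eliminated]
        sub = GeneMatrix(m.data[cols], m.classes, m.experiment_tag)
        cv = cross_validate(
            sub, learner, k=cfg.cv_folds, seed=_derive_seed(cfg.seed, iterations)
        )
        model = learner.fit(sub.data, sub.classes, seed=_derive_seed(cfg.seed, iterations))
        return model, cv.mean_macro_f

    if cfg.mode == "standard":
        removed: set[str] = set()
        stop_reason = "exhausted"
        while True:
            reason = out_of_budget()
            if reason:
                stop_reason = reason
                break
            if len(removed) >= len(all_features):
                stop_reason = "exhausted"
                break
            model, f = train(frozenset(removed))
            iterations += 1
            if f < cfg.f_threshold:
                stop_reason = "below_threshold"
                break
            feats = model.features
            archived.append(ArchivedModel(model, frozenset(removed), f))
            seen_rule_sets.add(feats)
            if not feats:
                # degenerate model uses no features; elimination cannot progress
                stop_reason = "exhausted"
                break
            removed |= feats
        return CamurRun(archived, iterations, stop_reason)

    # loose mode
    pool: set[str] = set()
    queue: list[frozenset[str]] = []
    enqueued: set[frozenset[str]] = set()
    processed: set[frozenset[str]] = set()

    def enqueue(subset: frozenset[str]) -> None:
        if subset and subset not in enqueued and len(queue) < cfg.max_iterations:
            queue.append(subset)
            enqueued.add(subset)

    def next_fallback() -> frozenset[str] | None:
        ordered_pool = sorted(pool)
        for size in range(1, len(ordered_pool) + 1):
            for combo in combinations(ordered_pool, size):
                subset = frozenset(combo)
                if subset not in processed and subset not in enqueued:
                    return subset
        return None

    def handle(eliminated: frozenset[str]) -> None:
        nonlocal iterations
        model, f = train(eliminated)
        iterations += 1
        processed.add(eliminated)
        feats = model.features
        if f >= cfg.f_threshold and feats and feats not in seen_rule_sets:
            archived.append(ArchivedModel(model, eliminated, f))
            seen_rule_sets.add(feats)
            pool.update(feats)
            enqueue(frozenset(eliminated | feats))
            for feat in sorted(feats):
                enqueue(frozenset({feat}))

    stop_reason = "exhausted"
    reason = out_of_budget()
    if reason:
        return CamurRun(archived, iterations, reason)
    handle(frozenset())
    while True:
        reason = out_of_budget()
        if reason:
            stop_reason = reason
            break
        if queue:
            subset = queue.pop(0)
        else:
            fallback = next_fallback()
            if fallback is None:
                stop_reason = "exhausted"
                break
            subset = fallback
            enqueued.add(subset)
        handle(subset)
    return CamurRun(archived, iterations, stop_reason)


def analyze_run(r: CamurRun) -> dict:
    """Summarize an archive: rules, literal/conjunction statistics, gene list.

    Returns a dict with ``rule_list`` (rendered rules across all models),
    ``literal_frequencies`` (Counter over (feature, op)), ``conjunction_list``
    (one entry per rule: tuple of literal strings), ``feature_pair_cooccurrence``
    (Counter over unordered feature pairs within a conjunction) and
    ``gene_list`` (sorted union of features over all rules).
    """
    rule_list: list[str] = []
    literal_frequencies: Counter = Counter()
    conjunction_list: list[tuple[str, ...]] = []
    pair_cooccurrence: Counter = Counter()
    genes: set[str] = set()
    for archived in r.models:
        for rule in archived.model.rules:
            rule_list.append(str(rule))
            conjunction_list.append(tuple(str(c) for c in rule.conditions))
            feats = sorted({c.feature for c in rule.conditions})
            genes.update(feats)
            for cond in rule.conditions:
                literal_frequencies[(cond.feature, cond.op)] += 1
            for a, b in combinations(feats, 2):
                pair_cooccurrence[(a, b)] += 1
    return {
        "rule_list": rule_list,
        "literal_frequencies": literal_frequencies,
        "conjunction_list": conjunction_list,
        "feature_pair_cooccurrence": pair_cooccurrence,
        "gene_list": sorted(genes),
    }
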