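"""Rule semantics and the sequential-covering learner, checked against
exhaustive-search oracles on small data."""

import numpy as np
import pandas as pd
import pytest

import omicrules as om
from omicrules.rule_induction import Condition, Rule, RuleModel

KIRP_RULE = Rule(
    (
        Condition("MAP3K11_dnaMeth", "<=", 12.3),
        Condition("PIP5KL1_dnaMeth", ">=", 2.1),
    ),
    "normal",
)
KIRP_COMBINED_MODEL = RuleModel(
    [KIRP_RULE, Rule((Condition("NELL1_rnaSeq", ">=", 437.3),), "normal")],
    "tumoral",
)


def frame(X, y, features=None):
    features = features or [f"f{j}" for j in range(np.shape(X)[1])]
    df = pd.DataFrame(np.asarray(X, dtype=float), columns=features,
                      index=[f"s{i}" for i in range(len(X))])
    return df, pd.Series(list(y), index=df.index)


def best_single_rule_accuracy(X, y):
    """Exhaustive oracle: best training accuracy of any one-condition rule
    (over both operators, all midpoint thresholds, all target/default pairs)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    classes = sorted(set(y))
    best = max(np.mean(y == c) for c in classes)  # rule-free default model
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j][~np.isnan(X[:, j])])
        for t in (vals[:-1] + vals[1:]) / 2:
            for covered in (X[:, j] <= t, X[:, j] >= t):
                covered = np.where(np.isnan(X[:, j]), False, covered)
                for target in classes:
                    for default in classes:
                        pred = np.where(covered, target, default)
                        best = max(best, float(np.mean(pred == y)))
    return best


class TestRuleSemantics:
    def test_conjunction_satisfied(self):
        assert KIRP_RULE.covers({"MAP3K11_dnaMeth": 10.0, "PIP5KL1_dnaMeth": 3.0})

    def test_missing_value_never_covered(self):
        assert not KIRP_RULE.covers({"MAP3K11_dnaMeth": 10.0})
        assert not KIRP_RULE.covers(
            {"MAP3K11_dnaMeth": 10.0, "PIP5KL1_dnaMeth": float("nan")}
        )

    def test_empty_conjunction_covers_everything(self):
        assert Rule((), "normal").covers({})

    def test_first_match_prediction(self):
        sample = {"MAP3K11_dnaMeth": 12.0, "PIP5KL1_dnaMeth": 2.5}
        assert KIRP_COMBINED_MODEL.predict(sample) == "normal"

    def test_default_when_no_rule_fires(self):
        sample = {"MAP3K11_dnaMeth": 20.0, "PIP5KL1_dnaMeth": 0.0,
                  "NELL1_rnaSeq": 10.0}
        assert KIRP_COMBINED_MODEL.predict(sample) == "tumoral"

    def test_ruleless_model_always_default(self):
        assert RuleModel([], "tumoral").predict({"x": 1.0}) == "tumoral"

    def test_json_round_trip(self):
        again = RuleModel.from_dict(KIRP_COMBINED_MODEL.to_dict())
        assert again.rules == KIRP_COMBINED_MODEL.rules
        assert again.default_class == KIRP_COMBINED_MODEL.default_class

    def test_render_matches_rule_style(self):
        text = KIRP_COMBINED_MODEL.render()
        assert "(MAP3K11_dnaMeth <= 12.3) and (PIP5KL1_dnaMeth >= 2.1) => class=normal" in text
        assert text.splitlines()[-2] == "=> class=tumoral"


class TestLearner:
    def test_separable_1d_single_threshold_rule(self):
        df, y = frame([[1], [2], [3], [10], [11]],
                      ["A", "A", "A", "B", "B"])
        model = om.learn_ruleset((df, y), om.RipperParams(seed=0))
        assert np.mean(model.predict_frame(df) == y.to_numpy()) == 1.0
        # the minority class B is separated by one threshold between 3 and 10
        (rule,) = model.rules
        (cond,) = rule.conditions
        assert rule.target_class == "B"
        assert 3.0 < cond.threshold < 10.0

    def test_single_class_degenerate_model(self):
        df, y = frame([[1], [2]], ["tumoral", "tumoral"])
        model = om.learn_ruleset((df, y))
        assert model.rules == [] and model.default_class == "tumoral"

    def test_planted_conjunction_recovered(self):
        # class "pos" iff f0 <= 5 and f1 >= 5; verified against exhaustive
        # enumeration of all 2-condition conjunctions over midpoint thresholds
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 10, size=(40, 2)).round(2)
        planted = (X[:, 0] <= 5.0) & (X[:, 1] >= 5.0)
        if planted.sum() > (~planted).sum():  # keep "pos" the minority target
            planted = ~planted
        y = np.where(planted, "pos", "neg")
        df, ys = frame(X, y)
        model = om.learn_ruleset((df, ys), om.RipperParams(seed=0))
        covered = np.zeros(len(df), dtype=bool)
        for rule in model.rules:
            covered |= rule.covers_frame(df)
        assert np.array_equal(covered, planted)

    def test_all_missing_feature_ignored(self):
        df, y = frame([[np.nan, 1], [np.nan, 2], [np.nan, 10], [np.nan, 11]],
                      ["A", "A", "B", "B"])
        model = om.learn_ruleset((df, y))
        assert all(c.feature == "f1" for r in model.rules for c in r.conditions)
        assert np.mean(model.predict_frame(df) == y.to_numpy()) == 1.0

    def test_three_class_input_rejected(self):
        df, y = frame([[1], [2], [3]], ["A", "B", "C"])
        with pytest.raises(ValueError):
            om.learn_ruleset((df, y))

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(9)
        df, y = frame(rng.normal(size=(30, 5)),
                      rng.choice(["normal", "tumoral"], size=30))
        params = om.RipperParams(seed=4)
        m1 = om.learn_ruleset((df, y), params)
        m2 = om.learn_ruleset((df, y), params)
        assert m1.to_dict() == m2.to_dict()

    def test_train_f_matches_independent_recomputation(self):
        from omicrules.evaluation import confusion_counts, f_measure

        rng = np.random.default_rng(11)
        df, y = frame(rng.normal(size=(40, 3)),
                      rng.choice(["normal", "tumoral"], size=40))
        model = om.learn_ruleset((df, y), om.RipperParams(seed=2))
        pred = model.predict_frame(df)
        truth = y.to_numpy(dtype=object)
        expected = np.mean(
            [f_measure(confusion_counts(truth, pred, c))
             for c in ("normal", "tumoral")]
        )
        assert model.train_f_measure == pytest.approx(expected)

    @pytest.mark.parametrize("trial", range(40))
    def test_training_accuracy_bounded_below_by_single_rule_oracle(self, trial):
        """On every tiny dataset (<= 12 x 2) the learner's training accuracy
        must reach the best exhaustively-found single-condition rule."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 13))
        m = int(rng.integers(1, 3))
        X = rng.normal(size=(n, m)).round(2)
        y = rng.choice(["normal", "tumoral"], size=n)
        if len(set(y)) < 2:
            y[0] = "normal"
            y[1] = "tumoral"
        df, ys = frame(X, y)
        model = om.learn_ruleset((df, ys), om.RipperParams(seed=trial))
        acc = float(np.mean(model.predict_frame(df) == y))
        assert acc >= best_single_rule_accuracy(X, y) - 1e-12
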