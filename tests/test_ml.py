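"""TSTR classification, Shapley attribution agreement, equal opportunity."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

from ehrsynth.evaluate import (
    attribution_rank_agreement,
    death_flag_task,
    equal_opportunity,
    next_visit_code_task,
    revisit_30d_task,
    shap_attributions,
    tstr_evaluate,
)
from ehrsynth.evaluate.ml import GBM_PARAMS, TaskSpec
from ehrsynth.simulate import SimConfig, build_schema, simulate_cohort


@pytest.fixture(scope="module")
def cohort():
    cfg = SimConfig(n_patients=1200, seed=21)
    records, _ = simulate_cohort(cfg)
    return build_schema(cfg), records


def split3(records, n1, n2):
    return records[:n1], records[n1 : n1 + n2], records[n1 + n2 :]


class TestTstr:
    def test_identical_training_sets_give_identical_rows(self, cohort):
        schema, records = cohort
        task = revisit_30d_task()
        train, test, _ = split3(records, 700, 400)
        table, _ = tstr_evaluate(train, train, test, task, seed=3, schema=schema)
        real = table[table.training_data == "real"].iloc[0]
        synth = table[table.training_data == "synthetic"].iloc[0]
        for m in ("precision", "recall", "f1", "pr_auc", "roc_auc"):
            assert real[m] == synth[m]

    def test_null_labels_give_chance_auc(self, rng):
        """Labels independent of features: ROC-AUC must sit at 0.5."""
        n = 4000
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = (rng.uniform(size=n) < 0.3).astype(int)
        df = X.copy()
        df["__label__"] = y

        task = TaskSpec("null", lambda rec, s: [], ["a", "b"])
        from ehrsynth.evaluate.ml import _fit_gbm, _metric_row

        model = _fit_gbm(df[["a", "b"]][:3000], y[:3000], seed=0)
        scores = model.predict_proba(df[["a", "b"]][3000:])[:, 1]
        row = _metric_row(y[3000:], scores)
        assert row["roc_auc"] == pytest.approx(0.5, abs=0.04)

    def test_separable_task_is_perfect(self, rng):
        from ehrsynth.evaluate.ml import _fit_gbm, _metric_row

        n = 800
        x = rng.normal(size=n)
        y = (x > 0).astype(int)
        X = pd.DataFrame({"x": x})
        model = _fit_gbm(X, y, seed=0)
        row = _metric_row(y, model.predict_proba(X)[:, 1])
        assert row["f1"] == 1.0

    def test_single_class_training_rejected(self, cohort):
        schema, records = cohort
        from ehrsynth.evaluate.ml import _fit_gbm

        with pytest.raises(ValueError, match="single-class"):
            _fit_gbm(pd.DataFrame({"a": [1.0, 2.0]}), np.array([1, 1]), seed=0)

    def test_builtin_extractors_use_only_history(self, cohort):
        """The death-flag task must not leak the visit's own LOS/outcome."""
        schema, records = cohort
        for task in (next_visit_code_task(), death_flag_task(), revisit_30d_task()):
            df = task.table(records[:200], schema)
            assert "__label__" in df.columns
            assert set(task.features) <= set(df.columns)


def exhaustive_shapley(predict, x, background, features):
    """Brute-force Shapley values by coalition enumeration (<= 8 features).

    v(S) = E_background[f(x_S, X_notS)] using the interventional expectation.
    """
    M = len(features)
    phi = np.zeros(M)
    for i in range(M):
        rest = [j for j in range(M) if j != i]
        for size in range(M):
            for S in itertools.combinations(rest, size):
                w = (math.factorial(len(S)) * math.factorial(M - len(S) - 1)
                     / math.factorial(M))
                def value(cols):
                    Xb = background.copy()
                    for c in cols:
                        Xb[features[c]] = x[features[c]]
                    return float(predict(Xb).mean())
                phi[i] += w * (value(list(S) + [i]) - value(list(S)))
    return phi


class TestAttributions:
    def test_model_against_itself(self, cohort):
        schema, records = cohort
        task = revisit_30d_task()
        train, test, _ = split3(records, 700, 300)
        _, models = tstr_evaluate(train, train, test, task, seed=1, schema=schema)
        X = task.table(test, schema)[task.features]
        overlap, rho = attribution_rank_agreement(models["real"], models["real"], X)
        assert overlap == 10
        assert rho == pytest.approx(1.0)

    def test_tree_attributions_match_exhaustive_shapley_ranking(self, rng):
        """4-feature additive model: exact coalition enumeration is the
        oracle for the attribution ranking."""
        n = 3000
        X = pd.DataFrame({f"f{i}": rng.normal(size=n) for i in range(4)})
        y = (4 * X.f0 + 2 * X.f1 + 1 * X.f2 + 0.0 * X.f3
             + 0.1 * rng.normal(size=n))
        model = xgb.XGBRegressor(random_state=0, **GBM_PARAMS)
        model.fit(X, y)
        booster = model.get_booster()
        contrib = booster.predict(xgb.DMatrix(X[:50]), pred_contribs=True)
        mean_abs = np.abs(contrib[:, :-1]).mean(0)

        def predict(df):
            return model.predict(df[X.columns])

        oracle = np.zeros(4)
        background = X.sample(40, random_state=1).reset_index(drop=True)
        for k in range(20):
            oracle += np.abs(exhaustive_shapley(
                predict, X.iloc[k], background, list(X.columns)))
        assert list(np.argsort(-mean_abs)) == list(np.argsort(-oracle))

    def test_reversed_ranking_gives_minus_one_rho(self):
        from scipy.stats import spearmanr

        a = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        assert spearmanr(a, a[::-1]).statistic == pytest.approx(-1.0)


class _StubModel:
    def __init__(self, scores):
        self.scores = np.asarray(scores, float)

    def predict_proba(self, X):
        return np.column_stack([1 - self.scores, self.scores])


class TestEqualOpportunity:
    def test_identical_tpr_gives_zero_gap(self):
        y = np.array([1, 1, 1, 1, 0, 0])
        scores = np.array([0.9, 0.9, 0.9, 0.9, 0.1, 0.1])
        groups = np.array(["a", "b", "a", "b", "a", "b"])
        gap = equal_opportunity(_StubModel(scores), pd.DataFrame({"x": y}),
                                y, groups)
        assert gap == 0.0

    def test_known_tpr_difference(self):
        # group a: TPRs 0.9 -> predictions 9/10 positive; group b: 0.6
        y = np.ones(20, int)
        scores = np.concatenate([np.r_[np.full(9, 0.9), 0.1],
                                 np.r_[np.full(6, 0.9), np.full(4, 0.1)]])
        groups = np.array(["a"] * 10 + ["b"] * 10)
        gap = equal_opportunity(_StubModel(scores), pd.DataFrame({"x": y}),
                                y, groups)
        assert gap == pytest.approx(0.3)

    def test_group_independent_scores_small_gap(self, rng):
        n = 10_000
        y = (rng.uniform(size=n) < 0.4).astype(int)
        scores = np.where(y == 1, rng.uniform(0.3, 1.0, n), rng.uniform(0, 0.7, n))
        groups = rng.choice(["a", "b", "c"], size=n)
        gap = equal_opportunity(_StubModel(scores), pd.DataFrame({"x": y}),
                                y, groups)
        assert gap < 0.05

    def test_group_without_positives_excluded_with_warning(self):
        y = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.2, 0.1, 0.1])
        groups = np.array(["a", "a", "b", "b"])
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning, match="no positive"):
                equal_opportunity(_StubModel(scores), pd.DataFrame({"x": y}),
                                  y, groups)

    def test_invariant_to_ordering_and_relabeling(self, rng):
        n = 500
        y = (rng.uniform(size=n) < 0.5).astype(int)
        scores = rng.uniform(size=n)
        groups = rng.choice(["a", "b"], size=n)
        g1 = equal_opportunity(_StubModel(scores), pd.DataFrame({"x": y}), y, groups)
        perm = rng.permutation(n)
        g2 = equal_opportunity(_StubModel(scores[perm]),
                               pd.DataFrame({"x": y[perm]}), y[perm], groups[perm])
        relabeled = np.where(groups == "a", "z", "q")
        g3 = equal_opportunity(_StubModel(scores), pd.DataFrame({"x": y}), y,
                               relabeled)
        assert g1 == pytest.approx(g2) == pytest.approx(g3)
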