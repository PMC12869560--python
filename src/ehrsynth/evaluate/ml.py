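"""Machine-learning utility: train-on-synthetic/test-on-real (TSTR)
classification, tree-Shapley attribution rank agreement, and the equal
opportunity fairness gap."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence
import warnings

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import spearmanr
from sklearn.metrics import (
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from ..cohort import gap_days
from ..records import PatientRecord

GBM_PARAMS = dict(max_depth=4, n_estimators=200, learning_rate=0.1,
                  n_jobs=1, tree_method="hist")
THRESHOLD = 0.5


@dataclass
class TaskSpec:
    """A prediction task: an extractor mapping a patient record to zero or
    more (features, label) examples using only pre-outcome information."""

    name: str
    extractor: Callable[[PatientRecord, object], list[tuple[dict, int]]]
    features: list[str]
    group_fields: list[str] = field(default_factory=list)

    def table(self, records, schema=None) -> pd.DataFrame:
        rows = []
        for rec in records:
            for feats, label in self.extractor(rec, schema):
                row = dict(feats)
                row["__label__"] = int(label)
                rows.append(row)
        df = pd.DataFrame(rows)
        for f in self.features:
            if f not in df.columns:
                df[f] = np.nan
        return df


# --- built-in task extractors ---------------------------------------------


def _base_features(rec: PatientRecord, upto: int, schema) -> dict:
    """History features from visits [0, upto)."""
    visits = rec.visits[:upto]
    feats = {
        "age": rec.statics.get("age", np.nan),
        "gender_f": float(rec.statics.get("gender") == "F"),
        "n_prior_visits": float(len(visits)),
    }
    codes = [c for v in visits for c in v.codes]
    feats["n_prior_codes"] = float(len(codes))
    for fam in ("E11", "I21", "J45", "I63", "R07"):
        feats[f"hx_{fam}"] = float(any(c.startswith(fam) for c in codes))
    los = [v.continuous.get("total_los_hours") for v in visits]
    los = [x for x in los if x is not None]
    feats["prev_los"] = float(los[-1]) if los else np.nan
    if len(visits) >= 2 and schema is not None:
        g = gap_days(visits[-2], visits[-1], schema)
        feats["prev_gap_days"] = float(g) if g is not None else np.nan
    else:
        feats["prev_gap_days"] = np.nan
    return feats


def next_visit_code_task(code_prefix: str = "E16") -> TaskSpec:
    """Predict whether the next visit carries a target diagnosis family,
    among patients without a prior diagnosis from that family."""

    def extract(rec, schema):
        out = []
        for j in range(1, len(rec.visits)):
            history = rec.visits[:j]
            if any(c.startswith(code_prefix) for v in history for c in v.codes):
                break
            label = any(c.startswith(code_prefix) for c in rec.visits[j].codes)
            out.append((_base_features(rec, j, schema), int(label)))
            if label:
                break
        return out

    return TaskSpec(
        name=f"next_visit_{code_prefix}",
        extractor=extract,
        features=["age", "gender_f", "n_prior_visits", "n_prior_codes",
                  "hx_E11", "hx_I21", "hx_J45", "hx_I63", "hx_R07",
                  "prev_los", "prev_gap_days"],
        group_fields=["gender_f"],
    )


def death_flag_task(field_name: str = "disposition", level: str = "died") -> TaskSpec:
    """Predict an in-visit death flag from information at visit start."""

    def extract(rec, schema):
        out = []
        for j, v in enumerate(rec.visits):
            label = v.categoricals.get(field_name) == level
            feats = _base_features(rec, j, schema)
            feats["event_ed"] = float(v.event_type == "ED")
            out.append((feats, int(label)))
        return out

    return TaskSpec(
        name="in_visit_death",
        extractor=extract,
        features=["age", "gender_f", "n_prior_visits", "n_prior_codes",
                  "hx_E11", "hx_I21", "hx_J45", "hx_I63", "hx_R07",
                  "prev_los", "prev_gap_days", "event_ed"],
        group_fields=["gender_f"],
    )


def revisit_30d_task() -> TaskSpec:
    """Predict whether a visit is followed by another within 30 days."""

    def extract(rec, schema):
        out = []
        for j, v in enumerate(rec.visits[:-1]):
            g = gap_days(v, rec.visits[j + 1], schema) if schema else None
            if g is None:
                continue
            feats = _base_features(rec, j + 1, schema)
            out.append((feats, int(g <= 30)))
        return out

    return TaskSpec(
        name="revisit_30d",
        extractor=extract,
        features=["age", "gender_f", "n_prior_visits", "n_prior_codes",
                  "hx_E11", "hx_I21", "hx_J45", "hx_I63", "hx_R07",
                  "prev_los", "prev_gap_days"],
        group_fields=["gender_f"],
    )


BUILTIN_TASKS = {
    "next_visit_code": next_visit_code_task,
    "in_visit_death": death_flag_task,
    "revisit_30d": revisit_30d_task,
}


# --- TSTR ------------------------------------------------------------------


def _fit_gbm(X: pd.DataFrame, y: np.ndarray, seed: int) -> xgb.XGBClassifier:
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are single-class")
    model = xgb.XGBClassifier(random_state=seed, **GBM_PARAMS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def _metric_row(y_true, scores) -> dict:
    pred = (scores >= THRESHOLD).astype(int)
    return {
        "precision": float(precision_score(y_true, pred, zero_division=0)),
        "recall": float(recall_score(y_true, pred, zero_division=0)),
        "f1": float(f1_score(y_true, pred, zero_division=0)),
        "pr_auc": float(average_precision_score(y_true, scores)),
        "roc_auc": float(roc_auc_score(y_true, scores)),
    }


def tstr_evaluate(train_real, train_synth, test_real, task: TaskSpec,
                  seed: int = 0, schema=None) -> tuple[pd.DataFrame, dict]:
    """Gradient-boosted classifiers trained on real, synthetic and combined
    data, all scored on the held-out real test set.

    Returns the metric table (one row per training condition) and the
    fitted models keyed by condition.
    """
    feats = task.features
    tr = task.table(train_real, schema)
    ts = task.table(train_synth, schema)
    te = task.table(test_real, schema)
    if te["__label__"].nunique() < 2:
        raise ValueError("test labels are single-class")
    comb = pd.concat([tr, ts], ignore_index=True)
    models, rows = {}, []
    for cond, df in (("real", tr), ("synthetic", ts), ("real+synthetic", comb)):
        model = _fit_gbm(df[feats], df["__label__"].values, seed)
        scores = model.predict_proba(te[feats])[:, 1]
        rows.append({"training_data": cond, **_metric_row(te["__label__"].values, scores)})
        models[cond] = model
    return pd.DataFrame(rows), models


# --- attributions ----------------------------------------------------------


def shap_attributions(model: xgb.XGBClassifier, X: pd.DataFrame) -> np.ndarray:
    """Mean |Shapley attribution| per feature (exact tree-path algorithm)."""
    booster = model.get_booster()
    dm = xgb.DMatrix(X, feature_names=list(X.columns))
    contrib = booster.predict(dm, pred_contribs=True)
    return np.abs(contrib[:, :-1]).mean(0)  # last column is the bias term


def attribution_rank_agreement(model_real, model_synth, X_test: pd.DataFrame,
                               top_k: int = 10) -> tuple[int, float]:
    """Top-k overlap count and Spearman rank correlation of per-feature
    mean |Shapley| attributions computed on the real test set."""
    a = shap_attributions(model_real, X_test)
    b = shap_attributions(model_synth, X_test)
    if len(a) != len(b):
        raise ValueError("models have mismatched feature lists")
    k = min(top_k, len(a))
    top_a = set(np.argsort(-a)[:k])
    top_b = set(np.argsort(-b)[:k])
    rho = float(spearmanr(a, b).statistic)
    return len(top_a & top_b), rho


# --- fairness --------------------------------------------------------------


def equal_opportunity(model, X_test: pd.DataFrame, y_test: np.ndarray,
                      groups: Sequence) -> float:
    """Equal-opportunity gap: max - min true-positive rate across groups at
    the 0.5 threshold.  Groups without positive cases are excluded."""
    groups = np.asarray(groups)
    scores = model.predict_proba(X_test)[:, 1]
    pred = scores >= THRESHOLD
    y = np.asarray(y_test).astype(bool)
    tprs = {}
    for g in pd.unique(groups):
        m = (groups == g) & y
        if m.sum() == 0:
            warnings.warn(f"group {g!r} has no positive cases; excluded")
            continue
        tprs[g] = float(pred[m].mean())
    if len(tprs) < 2:
        raise ValueError("need at least two groups with positive cases")
    vals = list(tprs.values())
    return float(max(vals) - min(vals))
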