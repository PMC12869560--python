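"""Statistical-modelling utility: paired coefficient comparison and
demographic prevalence curves."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .realism import _visit_frame


@dataclass
class ModelSpec:
    """A regression specification fitted identically to both cohorts.

    ``family`` is ``linear`` or ``binomial``; ``group`` adds a random
    intercept (linear models only — fitted with a linear mixed model).
    ``factor_orderings`` lists factor variables whose level-estimate
    ordering should be compared between cohorts.
    """

    formula: str
    family: str = "linear"
    group: Optional[str] = None
    factor_orderings: list[str] = field(default_factory=list)


def _fit(df: pd.DataFrame, spec: ModelSpec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if spec.family == "linear":
            if spec.group:
                model = smf.mixedlm(spec.formula, df.dropna(
                    subset=_formula_cols(spec, df)), groups=df.dropna(
                    subset=_formula_cols(spec, df))[spec.group])
                return model.fit(reml=True)
            return smf.ols(spec.formula, df).fit()
        if spec.family == "binomial":
            if spec.group:
                warnings.warn("random intercepts unsupported for binomial; "
                              "fitting a plain GLM")
            return smf.glm(spec.formula, df, family=sm.families.Binomial()).fit()
    raise ValueError(f"unknown family {spec.family!r}")


def _formula_cols(spec: ModelSpec, df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c in spec.formula]
    if spec.group and spec.group in df.columns:
        cols.append(spec.group)
    return cols


def coefficient_comparison(real, synth, spec: ModelSpec, schema=None,
                           variables: Sequence[str] = ()) -> pd.DataFrame:
    """Fit the same specification to both cohorts and pair the estimates.

    ``real``/``synth`` may be record lists (turned into visit frames) or
    prepared DataFrames.  The result holds estimates, 95% intervals, a
    sign-agreement flag per term, and per-factor ordering-preserved flags.
    """
    df_r = real if isinstance(real, pd.DataFrame) else _visit_frame(real, schema, variables)
    df_s = synth if isinstance(synth, pd.DataFrame) else _visit_frame(synth, schema, variables)

    rows = []
    fits = {}
    for label, df in (("real", df_r), ("synthetic", df_s)):
        try:
            fits[label] = _fit(df, spec)
        except Exception as e:  # noqa: BLE001 - non-convergence is reported, not raised
            fits[label] = None
            warnings.warn(f"{label} fit failed: {e}")
    if fits["real"] is None or fits["synthetic"] is None:
        raise RuntimeError("model failed to converge on one of the cohorts")

    pr, ps = fits["real"].params, fits["synthetic"].params
    ci_r, ci_s = fits["real"].conf_int(), fits["synthetic"].conf_int()
    for term in pr.index:
        if term not in ps.index:
            continue
        er, es = float(pr[term]), float(ps[term])
        rows.append({
            "term": term,
            "estimate_real": er,
            "ci_low_real": float(ci_r.loc[term, 0]),
            "ci_high_real": float(ci_r.loc[term, 1]),
            "estimate_synth": es,
            "ci_low_synth": float(ci_s.loc[term, 0]),
            "ci_high_synth": float(ci_s.loc[term, 1]),
            "sign_agrees": bool(np.sign(er) == np.sign(es)) or (er == es == 0),
        })
    out = pd.DataFrame(rows)
    out.attrs["ordering_preserved"] = {}
    for factor in spec.factor_orderings:
        terms = [t for t in pr.index if t.startswith(f"C({factor})") or
                 t.startswith(f"{factor}[")]
        terms = [t for t in terms if t in ps.index]
        if len(terms) >= 2:
            order_r = np.argsort([pr[t] for t in terms])
            order_s = np.argsort([ps[t] for t in terms])
            out.attrs["ordering_preserved"][factor] = bool((order_r == order_s).all())
    return out


def prevalence_curves(real, synth, condition_code_sets: dict,
                      age_bins: Sequence[float]) -> dict:
    """Smoothed condition prevalence by gender and age in both cohorts.

    A binned logistic smoother (binomial GLM on age-bin midpoint, linear +
    quadratic) is fitted per gender; the per-condition summary is the
    maximum absolute prevalence gap between cohorts over the grid.
    """
    age_bins = np.asarray(age_bins, float)
    mids = (age_bins[:-1] + age_bins[1:]) / 2

    def patient_frame(records):
        rows = []
        for r in records:
            age = r.statics.get("age")
            if not isinstance(age, (int, float)):
                continue
            codes = {c for v in r.visits for c in v.codes}
            row = {"age": float(age), "gender": r.statics.get("gender", "?")}
            for name, cset in condition_code_sets.items():
                row[name] = int(any(
                    any(c.startswith(p) for p in cset) for c in codes))
            rows.append(row)
        return pd.DataFrame(rows)

    def curves(df):
        out = {}
        df = df.copy()
        df["bin"] = np.clip(np.digitize(df["age"], age_bins) - 1, 0, len(mids) - 1)
        for name in condition_code_sets:
            for g, sub in df.groupby("gender"):
                agg = sub.groupby("bin")[name].agg(["sum", "count"])
                if agg["sum"].sum() == 0 or len(agg) < 3:
                    out[(name, g)] = np.full(len(mids), sub[name].mean())
                    continue
                X = np.column_stack([np.ones(len(agg)), mids[agg.index],
                                     mids[agg.index] ** 2])
                y = np.column_stack([agg["sum"], agg["count"] - agg["sum"]])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
                        Xg = np.column_stack([np.ones(len(mids)), mids, mids**2])
                        out[(name, g)] = fit.predict(Xg)
                    except Exception:  # noqa: BLE001
                        out[(name, g)] = np.full(len(mids), sub[name].mean())
        return out

    cr = curves(patient_frame(real))
    cs = curves(patient_frame(synth))
    result = {"age_grid": mids.tolist(), "curves_real": {}, "curves_synth": {},
              "max_gap": {}}
    for key, vals in cr.items():
        result["curves_real"]["|".join(map(str, key))] = np.asarray(vals).tolist()
    for key, vals in cs.items():
        result["curves_synth"]["|".join(map(str, key))] = np.asarray(vals).tolist()
    for name in condition_code_sets:
        gaps = []
        for key, vr in cr.items():
            if key[0] != name:
                continue
            vs = cs.get(key, np.zeros(len(mids)))
            gaps.append(np.max(np.abs(np.asarray(vr) - np.asarray(vs))))
        result["max_gap"][name] = float(max(gaps)) if gaps else float("nan")
    return result
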