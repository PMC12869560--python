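"""Aggregate realism/utility report comparing two cohorts."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ml import TaskSpec, attribution_rank_agreement, equal_opportunity, tstr_evaluate
from .realism import (
    bigram_r2,
    code_frequency_r2,
    conditional_occurrence,
    correlation_fidelity,
    summary_compare,
)
from .temporal import temporal_fidelity


@dataclass
class ComparisonReport:
    summary_table: Optional[pd.DataFrame] = None
    corr_real: Optional[pd.DataFrame] = None
    corr_synth: Optional[pd.DataFrame] = None
    corr_diff: Optional[pd.DataFrame] = None
    corr_max_abs_diff: float = float("nan")
    freq_r2: float = float("nan")
    retained_fraction: float = float("nan")
    bigram_r2_within: float = float("nan")
    bigram_r2_sequential: float = float("nan")
    conditional_occurrence: list = field(default_factory=list)
    tstr: Optional[pd.DataFrame] = None
    shap_top10_overlap: Optional[int] = None
    shap_rank_rho: float = float("nan")
    equal_opportunity_gaps: dict = field(default_factory=dict)
    temporal: dict = field(default_factory=dict)

    def metrics_dict(self) -> dict:
        d = {
            "corr_max_abs_diff": self.corr_max_abs_diff,
            "freq_r2": self.freq_r2,
            "retained_fraction": self.retained_fraction,
            "bigram_r2_within": self.bigram_r2_within,
            "bigram_r2_sequential": self.bigram_r2_sequential,
            "conditional_occurrence": self.conditional_occurrence,
            "shap_top10_overlap": self.shap_top10_overlap,
            "shap_rank_rho": self.shap_rank_rho,
            "equal_opportunity_gaps": self.equal_opportunity_gaps,
            "temporal": self.temporal,
        }
        if self.tstr is not None:
            d["tstr"] = self.tstr.to_dict(orient="records")
        return d

    def save(self, outdir) -> None:
        """Directory output: metrics.json + delimited tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "metrics.json", "w") as fh:
            json.dump(_jsonable(self.metrics_dict()), fh, indent=2)
        if self.summary_table is not None:
            self.summary_table.to_csv(outdir / "summary.csv")
        for name, df in (("corr_real", self.corr_real),
                         ("corr_synth", self.corr_synth),
                         ("corr_diff", self.corr_diff),
                         ("tstr", self.tstr)):
            if df is not None:
                df.to_csv(outdir / f"{name}.csv")


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def build_report(
    real,
    synth,
    schema,
    variables: Sequence[str] = (),
    dx_pairs: Sequence[tuple[Sequence[str], Sequence[str]]] = (),
    task: Optional[TaskSpec] = None,
    seed: int = 0,
    with_temporal: bool = True,
) -> ComparisonReport:
    """Run the full battery; ML utility requires a task with two-class
    labels in both cohorts, otherwise that section is skipped."""
    rep = ComparisonReport()
    rep.summary_table = summary_compare(real, synth, schema, variables or None)
    if len(variables) >= 2:
        cr, cs, cd, mx = correlation_fidelity(real, synth, schema, variables)
        rep.corr_real, rep.corr_synth, rep.corr_diff = cr, cs, cd
        rep.corr_max_abs_diff = mx
    rep.freq_r2, rep.retained_fraction = code_frequency_r2(real, synth)
    rep.bigram_r2_within = bigram_r2(real, synth, "within_visit")
    try:
        rep.bigram_r2_sequential = bigram_r2(real, synth, "sequential_visits")
    except ValueError:
        pass
    for index_set, outcome_set in dx_pairs:
        pr = conditional_occurrence(real, index_set, outcome_set)
        ps = conditional_occurrence(synth, index_set, outcome_set)
        rep.conditional_occurrence.append({
            "index": list(index_set), "outcome": list(outcome_set),
            "real_p_with": pr[0], "real_p_without": pr[1],
            "synth_p_with": ps[0], "synth_p_without": ps[1],
        })
    if task is not None:
        from ..cohort import split_cohort

        tr_real, te_real = split_cohort(real, (0.7, 0.3), seed=seed)[:2]
        try:
            table, models = tstr_evaluate(tr_real, synth, te_real, task,
                                          seed=seed, schema=schema)
            rep.tstr = table
            te_df = task.table(te_real, schema)
            X = te_df[task.features]
            overlap, rho = attribution_rank_agreement(
                models["real"], models["synthetic"], X)
            rep.shap_top10_overlap, rep.shap_rank_rho = overlap, rho
            for gf in task.group_fields:
                try:
                    rep.equal_opportunity_gaps[gf] = {
                        cond: equal_opportunity(models[cond], X,
                                                te_df["__label__"].values,
                                                te_df[gf].values)
                        for cond in models
                    }
                except ValueError:
                    pass
        except ValueError as e:
            rep.equal_opportunity_gaps["skipped"] = str(e)
    if with_temporal:
        try:
            rep.temporal = temporal_fidelity(real, synth)
        except ValueError:
            pass
    return rep
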