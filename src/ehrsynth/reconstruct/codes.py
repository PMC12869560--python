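"""Re-expansion of aggregated diagnosis codes.

Codes collapsed to two/three-character categories during modelling are
mapped back to full-resolution codes by sampling from the empirical
distribution of full codes within the category, stratified (by default by
gender), restoring the original code spectrum in the final output.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..cohort import POOLED, CodeAggregationMap


def expand_codes(aggregated_code: str, stratum, aggregation_map: CodeAggregationMap,
                 rng: np.random.Generator) -> str:
    """Draw a full code for an aggregated category.

    Codes that were never aggregated pass through unchanged; an unknown
    stratum falls back to the pooled table.
    """
    stratum = str(stratum)
    table = aggregation_map.empirical.get((aggregated_code, stratum))
    if table is None:
        table = aggregation_map.empirical.get((aggregated_code, POOLED))
    if table is None:
        if aggregated_code in aggregation_map.forward.values():
            warnings.warn(f"no empirical table for aggregated code {aggregated_code!r}")
        return aggregated_code
    codes = list(table.keys())
    probs = np.asarray(list(table.values()), float)
    probs = probs / probs.sum()
    return str(codes[rng.choice(len(codes), p=probs)])
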