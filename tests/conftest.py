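"""Shared fixtures: small simulated cohorts and prepared tokenizations."""

from __future__ import annotations

import numpy as np
import pytest

from ehrsynth.cohort import (
    aggregate_codes,
    build_vocab,
    discretize,
    schema_with_observed_codes,
    split_cohort,
)
from ehrsynth.schema import resolve_bands
from ehrsynth.simulate import SimConfig, build_schema, simulate_cohort


@pytest.fixture(scope="session")
def sim_small():
    """300-patient simulated cohort with truth record."""
    cfg = SimConfig(n_patients=300, seed=42)
    records, truth = simulate_cohort(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def prepared_small(sim_small):
    """Aggregated, band-resolved, tokenized version of the small cohort."""
    cfg, records, _ = sim_small
    agg, amap = aggregate_codes(records, min_count=50)
    schema = resolve_bands(schema_with_observed_codes(build_schema(cfg), agg), agg)
    train, val, test = split_cohort(agg, seed=5)
    vocab = build_vocab(schema)
    tok_train = discretize(train, schema, vocab)
    tok_val = discretize(val, schema, vocab)
    return {
        "config": cfg,
        "records": agg,
        "amap": amap,
        "schema": schema,
        "vocab": vocab,
        "train": train,
        "val": val,
        "test": test,
        "tok_train": tok_train,
        "tok_val": tok_val,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
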