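import numpy as np
import pandas as pd
import pytest

from lncsurv import (
    RegulonModel,
    SimulationConfig,
    simulate_regulatory_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Five-regulon cohort small enough for exhaustive checks."""
    cfg = SimulationConfig(
        n_lncrna=5, n_coding=500, n_samples_rnaseq=150,
        n_hazardous=1, n_protective=1, seed=3,
    )
    expr, truth = simulate_regulatory_cohort(cfg)
    return cfg, expr, truth


@pytest.fixture(scope="session")
def small_regulon_fit(small_cohort):
    cfg, expr, truth = small_cohort
    model = RegulonModel(expr, list(truth.activity.index))
    return model.fit(n_bootstrap=30, seed=1)


@pytest.fixture(scope="session")
def standard_cohort():
    """The documented standard cohort: 50 lncRNAs over 5,000 coding genes."""
    cfg = SimulationConfig(seed=11)
    expr, truth = simulate_regulatory_cohort(cfg)
    return cfg, expr, truth


@pytest.fixture(scope="session")
def standard_regulon_fit(standard_cohort):
    cfg, expr, truth = standard_cohort
    model = RegulonModel(expr, list(truth.activity.index))
    return model.fit(n_bootstrap=100, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_survival(time, event, dataset="D0"):
    n = len(time)
    return pd.DataFrame(
        {
            "sample": [f"P{i}" for i in range(n)],
            "time": np.asarray(time, dtype=float),
            "event": np.asarray(event, dtype=int),
            "dataset": dataset,
        }
    )
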