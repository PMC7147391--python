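import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from arsmr.synthetic import SimConfig, simulate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort with signal, shared across read-only tests."""
    cfg = SimConfig(n_samples=600, n_cpgs=60, frac_causal=0.5, seed=42)
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_design():
    """12-sample deterministic design with 2 covariates for oracle checks."""
    rng = np.random.default_rng(7)
    n = 12
    pred = rng.normal(size=n)
    c1 = rng.normal(size=n)
    c2 = rng.normal(size=n)
    x = pd.DataFrame({"const": 1.0, "pred": pred, "c1": c1, "c2": c2})
    y = 0.3 + 0.02 * pred - 0.01 * c1 + 0.005 * c2 + rng.normal(0, 0.01, n)
    return x, y
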