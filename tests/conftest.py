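import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import depval as dv

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")
from depval.outcome import attach_outcome


@pytest.fixture(scope="session")
def dev_cohort() -> pd.DataFrame:
    """Development-style cohort, all predictors varying (drug use 62.4%)."""
    return dv.generate_cohort(dv.development_config(seed=11, n_subjects=4000))


@pytest.fixture(scope="session")
def dev_model(dev_cohort) -> dv.RiskModel:
    X = dev_cohort[list(dv.DEFAULT_PREDICTOR_FREQS)]
    return dv.fit_pmle(X, dev_cohort["y"], lam=1.0)


@pytest.fixture(scope="session")
def val_sample() -> pd.DataFrame:
    """Filtered validation-style analysis sample (~600 subjects, prev ~0.2)."""
    cohort = dv.generate_cohort(dv.validation_config(seed=17, n_subjects=2500))
    included, _ = dv.select_analysis_sample(cohort)
    return attach_outcome(included)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def simulate_probs(
    rng: np.random.Generator, n: int, spread: float = 1.2, base: float = -1.0
):
    """True-probability benchmark: lp ~ Normal, y ~ Bernoulli(expit(lp))."""
    lp = base + spread * rng.standard_normal(n)
    p = 1.0 / (1.0 + np.exp(-lp))
    y = (rng.random(n) < p).astype(float)
    return p, y
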