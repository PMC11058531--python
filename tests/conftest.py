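import numpy as np
import pandas as pd
import pytest

from cohortshift import SamplerSettings
from scipy.special import expit


@pytest.fixture
def light_settings():
    """Small sampler budget for fast structural tests (not for inference quality)."""
    return SamplerSettings(n_ensembles=2, n_burn=400, n_steps=600, thin=3, seed=0)


def simulate_mixture_tau(
    seed: int,
    n_items: int = 56,
    n_countries: int = 8,
    slope: float = 1.0,
    mu_low: float = 0.25,
    mu_high: float = 0.85,
    phi: float = 20.0,
    sd_intercept: float = 0.3,
    sd_slope: float = 0.2,
) -> pd.DataFrame:
    """Tau values from two beta components with logit-linear mixing in z."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_countries):
        z = rng.normal(0, 1, n_items)
        u = rng.normal(0, sd_intercept)
        v = rng.normal(0, sd_slope)
        pi = expit(slope * z + u + v * z)
        hi = rng.random(n_items) < pi
        mu = np.where(hi, mu_high, mu_low)
        tau = rng.beta(mu * phi, (1 - mu) * phi)
        rows += [
            {"tau": t, "sensitivity_z": zz, "country": f"C{c}"} for t, zz in zip(tau, z)
        ]
    return pd.DataFrame(rows)


def simulate_change(
    seed: int,
    n_items: int = 56,
    n_countries: int = 8,
    slope: float = 0.3,
    intercept: float = -1.0,
    sigma: float = 0.4,
    sd_intercept: float = 0.2,
    sd_slope: float = 0.1,
) -> pd.DataFrame:
    """Positive abs-change outcomes, lognormal around a varying-slopes predictor."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_countries):
        z = rng.normal(0, 1, n_items)
        u = rng.normal(0, sd_intercept)
        v = rng.normal(0, sd_slope)
        y = np.exp(rng.normal(intercept + slope * z + u + v * z, sigma))
        rows += [
            {"abs_change_sd": yy, "sensitivity_z": zz, "country": f"C{c}"}
            for yy, zz in zip(y, z)
        ]
    return pd.DataFrame(rows)
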