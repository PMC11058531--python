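"""Hierarchical Bayesian models linking change and tau to issue sensitivity.

Three models, all with a population intercept and sensitivity slope plus
correlated country-varying intercept and slope deviations:

* **Change model** — absolute change (pooled-SD units, strictly positive)
  gets a lognormal likelihood; the linear predictor acts on the log scale.
* **Tau mixture model** — tau in (0,1) is bimodal in practice, so it is
  modelled as a two-component beta mixture (mean-precision parameterisation,
  component means ordered by construction so labels cannot switch); the
  log-odds that an observation comes from the *high*-tau component is the
  linear predictor.  The population slope of that mixing regression is the
  headline quantity: positive means more sensitive issues change more via
  cohort replacement.
* **Gaussian tau model** — a plain normal-likelihood regression of tau on
  sensitivity, kept as a robustness check on the mixture's direction.

Priors are weakly informative on the standardised scales: Normal(0,1) for
population coefficients, half-Normal(1) for group SDs and residual SDs,
LKJ(2) on the intercept-slope correlation, Gamma(2, 0.1) on beta precisions
(mean 20), Normal(0,1.5) on the low component's logit mean and a lognormal
positive gap up to the high one.

Posteriors are drawn with the ensemble sampler in :mod:`cohortshift._mcmc`;
country deviations are sampled non-centred (unit normals scaled inside the
likelihood) to avoid the hierarchical funnel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logit

from ._mcmc import SamplerSettings, sample_posterior, summarise_chains

logger = logging.getLogger(__name__)

__all__ = [
    "PosteriorSummary",
    "SamplerSettings",
    "fit_change_model",
    "fit_tau_mixture_model",
    "fit_tau_gaussian_model",
    "predict_curves",
    "default_grid",
    "sample_prior_predictive",
]

#: minimum rows for the mixture to be identifiable in practice
MIN_MIXTURE_ROWS = 20

_THETA_GUARD = 30.0  # unconstrained coordinates beyond this are outside any prior mass


def default_grid() -> np.ndarray:
    """Standardised-sensitivity grid: -1.5 to +1.5 SD in steps of 0.25."""
    return np.round(np.arange(-1.5, 1.5 + 1e-9, 0.25), 4)


# ---------------------------------------------------------------------------
# shared linear-predictor core
# ---------------------------------------------------------------------------

class _HierCore:
    """Index bookkeeping + prior + linear predictor for the varying-slopes block.

    Unconstrained layout: [a, b] then, when varying effects are on,
    [log sd_u, log sd_v, atanh rho, eps_u (C), eps_v (C)], then model extras.
    """

    def __init__(self, z: np.ndarray, codes: np.ndarray, n_countries: int, n_extras: int):
        self.z = z
        self.codes = codes
        self.C = n_countries
        self.varying = n_countries >= 2
        self.extra0 = (5 + 2 * n_countries) if self.varying else 2
        self.ndim = self.extra0 + n_extras

    def deviations(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Natural-scale country deviations (u, v), each (walkers, C)."""
        W = theta.shape[0]
        if not self.varying:
            return np.zeros((W, self.C)), np.zeros((W, self.C))
        C = self.C
        sd_u = np.exp(theta[:, 2:3])
        sd_v = np.exp(theta[:, 3:4])
        rho = np.tanh(theta[:, 4:5])
        eps_u = theta[:, 5 : 5 + C]
        eps_v = theta[:, 5 + C : 5 + 2 * C]
        u = sd_u * eps_u
        v = sd_v * (rho * eps_u + np.sqrt(1.0 - rho**2) * eps_v)
        return u, v

    def eta(self, theta: np.ndarray) -> np.ndarray:
        """Linear predictor (walkers, n_obs)."""
        a = theta[:, 0:1]
        b = theta[:, 1:2]
        u, v = self.deviations(theta)
        return a + b * self.z[None, :] + u[:, self.codes] + v[:, self.codes] * self.z[None, :]

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        lp = -0.5 * (theta[:, 0] ** 2 + theta[:, 1] ** 2)
        if self.varying:
            C = self.C
            for j in (2, 3):  # sd ~ half-Normal(1), sampled on the log scale
                sd = np.exp(theta[:, j])
                lp += -0.5 * sd**2 + theta[:, j]
            rho = np.tanh(theta[:, 4])
            with np.errstate(divide="ignore"):  # rho -> +-1 gets -inf, correctly
                lp += 2.0 * np.log1p(-(rho**2))  # LKJ(2) density + tanh Jacobian
            lp += -0.5 * np.sum(theta[:, 5 : 5 + 2 * C] ** 2, axis=1)
        return lp


def _guarded(log_prob):
    def inner(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        out = np.full(theta.shape[0], -np.inf)
        ok = np.all(np.abs(theta) < _THETA_GUARD, axis=1)
        if ok.any():
            out[ok] = log_prob(theta[ok])
        return out

    return inner


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Draws, summaries and diagnostics of one fitted hierarchical model."""

    model: str
    params: pd.DataFrame
    draws: dict[str, np.ndarray]
    diagnostics: dict
    countries: list[str]
    metadata: dict = field(default_factory=dict)
    curves: pd.DataFrame | None = None

    def slope_mass_above_zero(self) -> float:
        """Posterior probability that the population sensitivity slope is > 0."""
        d = self.draws["slope_sensitivity"]
        return float(np.mean(d > 0))


def _finalise(
    model: str,
    core: _HierCore,
    chains: np.ndarray,
    accept: float,
    countries: list[str],
    extra_names: dict[str, callable],
    settings: SamplerSettings,
    metadata: dict,
) -> PosteriorSummary:
    """Build natural-scale named chains, diagnostics and the summary object."""
    named: dict[str, np.ndarray] = {
        "intercept": chains[..., 0],
        "slope_sensitivity": chains[..., 1],
    }
    if core.varying:
        named["sd_country_intercept"] = np.exp(chains[..., 2])
        named["sd_country_slope"] = np.exp(chains[..., 3])
        named["cor_country"] = np.tanh(chains[..., 4])
    for name, fn in extra_names.items():
        named[name] = fn(chains)
    if core.varying:
        flat = chains.reshape(-1, chains.shape[-1])
        u, v = core.deviations(flat)
        shape = chains.shape[:2]
        for i, c in enumerate(countries):
            named[f"country_intercept[{c}]"] = u[:, i].reshape(shape)
            named[f"country_slope[{c}]"] = v[:, i].reshape(shape)

    params = summarise_chains(named)
    max_rhat = float(params["rhat"].max())
    diagnostics = {
        "max_rhat": max_rhat,
        "min_ess_bulk": float(params["ess_bulk"].min()),
        "mean_acceptance": accept,
        "n_chains": int(chains.shape[0]),
        "n_draws_per_chain": int(chains.shape[1]),
        "converged": bool(max_rhat < settings.rhat_threshold),
        "sampler": "affine-invariant ensemble",
    }
    if not diagnostics["converged"]:
        warnings.warn(
            f"{model}: max R-hat {max_rhat:.4f} exceeds {settings.rhat_threshold}; "
            "treat posterior summaries with caution",
            stacklevel=3,
        )
    draws = {k: v.reshape(-1) for k, v in named.items()}
    return PosteriorSummary(
        model=model,
        params=params,
        draws=draws,
        diagnostics=diagnostics,
        countries=countries,
        metadata=metadata,
    )


def _prepare_frame(data: pd.DataFrame, outcome: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    for col in (outcome, "sensitivity_z", "country"):
        if col not in data.columns:
            raise ValueError(f"model data lacks required column {col!r}")
    y = data[outcome].to_numpy(dtype=float)
    z = data["sensitivity_z"].to_numpy(dtype=float)
    cats = pd.Categorical(data["country"])
    codes = cats.codes.astype(int)
    return y, z, codes, list(cats.categories)


# ---------------------------------------------------------------------------
# model A: lognormal change regression
# ---------------------------------------------------------------------------

def fit_change_model(
    data: pd.DataFrame,
    settings: SamplerSettings | None = None,
    zero_handling: str = "error",
    floor: float = 1e-3,
) -> PosteriorSummary:
    """Lognormal varying-slopes regression of absolute change on sensitivity.

    ``data`` needs columns ``abs_change_sd`` (> 0), ``sensitivity_z`` and
    ``country``.  Non-positive outcomes are rejected (``zero_handling=
    "error"``), dropped (``"drop"``), or floored at ``floor`` (``"floor"``);
    either remedy is logged.  With a single country the model falls back to
    no varying effects with a warning.
    """
    settings = settings or SamplerSettings()
    y, z, codes, countries = _prepare_frame(data, "abs_change_sd")
    bad = y <= 0
    n_dropped = 0
    if bad.any():
        if zero_handling == "error":
            raise ValueError(
                f"{bad.sum()} non-positive abs_change_sd values; a lognormal likelihood "
                "requires y > 0 — pass zero_handling='drop' or 'floor'"
            )
        if zero_handling == "drop":
            logger.warning("dropping %d non-positive change values", bad.sum())
            n_dropped = int(bad.sum())
            y, z, codes = y[~bad], z[~bad], codes[~bad]
        elif zero_handling == "floor":
            logger.warning("flooring %d non-positive change values at %g", bad.sum(), floor)
            y = np.maximum(y, floor)
        else:
            raise ValueError(f"unknown zero_handling {zero_handling!r}")
    return _fit_location_scale(
        "change_lognormal", np.log(y), z, codes, countries, settings,
        metadata={"likelihood": "lognormal", "n_obs": len(y), "n_dropped": n_dropped},
    )


def fit_tau_gaussian_model(
    data: pd.DataFrame, settings: SamplerSettings | None = None
) -> PosteriorSummary:
    """Gaussian robustness regression of tau on sensitivity (same structure)."""
    settings = settings or SamplerSettings()
    data = _drop_undefined_tau(data)
    y, z, codes, countries = _prepare_frame(data, "tau")
    return _fit_location_scale(
        "tau_gaussian", y, z, codes, countries, settings,
        metadata={"likelihood": "gaussian", "n_obs": len(y)},
    )


def _fit_location_scale(
    model: str,
    y_lin: np.ndarray,
    z: np.ndarray,
    codes: np.ndarray,
    countries: list[str],
    settings: SamplerSettings,
    metadata: dict,
) -> PosteriorSummary:
    """Shared machinery: Normal likelihood for ``y_lin`` given eta and sigma."""
    C = len(countries)
    if C < 2:
        warnings.warn(f"{model}: single country — fitting without varying effects")
    core = _HierCore(z, codes, C, n_extras=1)
    isig = core.extra0

    def log_prob(theta: np.ndarray) -> np.ndarray:
        lp = core.log_prior(theta)
        sigma = np.exp(theta[:, isig])
        lp += -0.5 * sigma**2 + theta[:, isig]  # half-Normal(1), log-scale Jacobian
        eta = core.eta(theta)
        resid = y_lin[None, :] - eta
        ll = -0.5 * np.sum((resid / sigma[:, None]) ** 2, axis=1) - y_lin.size * np.log(sigma)
        return lp + ll

    slope, icept = np.polyfit(z, y_lin, 1) if np.ptp(z) > 0 else (0.0, float(y_lin.mean()))
    resid_sd = float(np.std(y_lin - (icept + slope * z))) or 0.1
    center = np.zeros(core.ndim)
    center[0], center[1] = icept, slope
    if core.varying:
        center[2] = center[3] = np.log(0.3)
    center[isig] = np.log(max(resid_sd, 0.05))

    chains, accept = sample_posterior(_guarded(log_prob), center, settings)
    return _finalise(
        model, core, chains, accept, countries,
        {"sigma": lambda ch: np.exp(ch[..., isig])},
        settings, metadata,
    )


# ---------------------------------------------------------------------------
# model B: two-component beta mixture for tau
# ---------------------------------------------------------------------------

def _drop_undefined_tau(data: pd.DataFrame) -> pd.DataFrame:
    n0 = len(data)
    if "tau_defined" in data.columns:
        data = data.loc[data["tau_defined"].astype(bool)]
    data = data.loc[np.isfinite(data["tau"].astype(float))]
    if len(data) < n0:
        logger.info("dropped %d rows with undefined tau", n0 - len(data))
    return data.reset_index(drop=True)


def _adjust_boundaries(tau: np.ndarray) -> tuple[np.ndarray, int]:
    """Shrink exact 0/1 values by the standard (tau*(n-1)+0.5)/n adjustment."""
    n = tau.size
    at_edge = (tau <= 0.0) | (tau >= 1.0)
    out = tau.copy()
    out[at_edge] = (tau[at_edge] * (n - 1) + 0.5) / n
    return out, int(at_edge.sum())


def _beta_logpdf(x_log: np.ndarray, x_log1m: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Beta log-density in mean-precision form; mu, phi are (walkers, 1)."""
    alpha = mu * phi
    beta = (1.0 - mu) * phi
    return (alpha - 1.0) * x_log + (beta - 1.0) * x_log1m - betaln(alpha, beta)


def fit_tau_mixture_model(
    data: pd.DataFrame, settings: SamplerSettings | None = None
) -> PosteriorSummary:
    """Two-beta finite mixture for tau with sensitivity-dependent mixing.

    The mixing weight attached to the *higher*-mean component follows
    ``logit(pi) = intercept + slope * sensitivity_z + country deviations``;
    component means are ordered by construction (the high mean is the low
    mean plus a positive gap on the logit scale), so labels cannot switch.
    Rows with undefined tau are dropped (logged); exact-boundary tau values
    are shrunk into (0,1) before likelihood evaluation.
    """
    settings = settings or SamplerSettings()
    data = _drop_undefined_tau(data)
    if len(data) < MIN_MIXTURE_ROWS:
        raise ValueError(
            f"only {len(data)} defined tau values; a two-component mixture is not "
            f"identifiable below ~{MIN_MIXTURE_ROWS} — pool more items/countries "
            "or fit the Gaussian model instead"
        )
    tau, z, codes, countries = _prepare_frame(data, "tau")
    tau, n_adjusted = _adjust_boundaries(tau)
    C = len(countries)
    if C < 2:
        warnings.warn("tau_mixture: single country — fitting without varying effects")
    core = _HierCore(z, codes, C, n_extras=4)
    i0 = core.extra0  # l1 (logit low mean), log gap, log phi_low, log phi_high

    t_log = np.log(tau)
    t_log1m = np.log1p(-tau)

    def log_prob(theta: np.ndarray) -> np.ndarray:
        lp = core.log_prior(theta)
        l1 = theta[:, i0]
        g = theta[:, i0 + 1]
        tp1 = theta[:, i0 + 2]
        tp2 = theta[:, i0 + 3]
        lp += -0.5 * (l1 / 1.5) ** 2 - 0.5 * g**2
        lp += 2.0 * tp1 - 0.1 * np.exp(tp1)  # Gamma(2, 0.1) on phi, log-scale
        lp += 2.0 * tp2 - 0.1 * np.exp(tp2)
        mu_low = expit(l1)[:, None]
        mu_high = expit(l1 + np.exp(g))[:, None]
        phi_low = np.exp(tp1)[:, None]
        phi_high = np.exp(tp2)[:, None]
        eta = core.eta(theta)
        log_pi = -np.logaddexp(0.0, -eta)  # P(high component)
        log_1mpi = -np.logaddexp(0.0, eta)
        lp_low = _beta_logpdf(t_log[None, :], t_log1m[None, :], mu_low, phi_low)
        lp_high = _beta_logpdf(t_log[None, :], t_log1m[None, :], mu_high, phi_high)
        ll = np.sum(np.logaddexp(log_1mpi + lp_low, log_pi + lp_high), axis=1)
        return lp + ll

    # moment-style init: split tau at its median on the logit scale
    lt = logit(np.clip(tau, 1e-4, 1 - 1e-4))
    med = np.median(lt)
    lo, hi = lt[lt <= med], lt[lt > med]
    l1_0 = float(np.clip(lo.mean(), -3, 3))
    gap_0 = max(float(hi.mean() - lo.mean()), 0.5)
    center = np.zeros(core.ndim)
    if core.varying:
        center[2] = center[3] = np.log(0.3)
    center[i0] = l1_0
    center[i0 + 1] = np.log(gap_0)
    center[i0 + 2] = center[i0 + 3] = np.log(10.0)

    chains, accept = sample_posterior(_guarded(log_prob), center, settings)
    extras = {
        "mu_low": lambda ch: expit(ch[..., i0]),
        "mu_high": lambda ch: expit(ch[..., i0] + np.exp(ch[..., i0 + 1])),
        "phi_low": lambda ch: np.exp(ch[..., i0 + 2]),
        "phi_high": lambda ch: np.exp(ch[..., i0 + 3]),
    }
    return _finalise(
        "tau_mixture", core, chains, accept, countries, extras, settings,
        metadata={
            "likelihood": "beta mixture (ordered means)",
            "n_obs": len(tau),
            "n_boundary_adjusted": n_adjusted,
        },
    )


# ---------------------------------------------------------------------------
# prediction curves
# ---------------------------------------------------------------------------

def _country_eta(summary: PosteriorSummary, country: str, grid: np.ndarray) -> np.ndarray:
    a = summary.draws["intercept"][:, None]
    b = summary.draws["slope_sensitivity"][:, None]
    ui = summary.draws.get(f"country_intercept[{country}]")
    vi = summary.draws.get(f"country_slope[{country}]")
    u = ui[:, None] if ui is not None else 0.0
    v = vi[:, None] if vi is not None else 0.0
    return a + u + (b + v) * grid[None, :]


def predict_curves(summary: PosteriorSummary, grid: np.ndarray | None = None) -> pd.DataFrame:
    """Posterior-mean predicted outcome per country over a sensitivity grid.

    Predictions are on the outcome scale: ``exp(eta + sigma^2/2)`` for the
    lognormal change model, ``eta`` for the Gaussian model, and the mixture
    mean ``pi * mu_high + (1 - pi) * mu_low`` for the tau mixture.  The
    result is also attached to ``summary.curves``.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if np.any(np.abs(grid) > 3.0):
        warnings.warn("prediction grid extends beyond +/-3 SD of sensitivity: extrapolation")
    rows = []
    for country in summary.countries:
        eta = _country_eta(summary, country, grid)
        if summary.model == "change_lognormal":
            sigma = summary.draws["sigma"][:, None]
            pred = np.exp(eta + 0.5 * sigma**2)
        elif summary.model == "tau_mixture":
            pi = expit(eta)
            mu_lo = summary.draws["mu_low"][:, None]
            mu_hi = summary.draws["mu_high"][:, None]
            pred = pi * mu_hi + (1.0 - pi) * mu_lo
        else:
            pred = eta
        mean_pred = pred.mean(axis=0)
        rows.extend(
            {
                "model": summary.model,
                "country": country,
                "sensitivity_z": float(g),
                "prediction": float(p),
            }
            for g, p in zip(grid, mean_pred)
        )
    curves = pd.DataFrame(rows)
    summary.curves = curves
    return curves


# ---------------------------------------------------------------------------
# prior predictive
# ---------------------------------------------------------------------------

def sample_prior_predictive(model: str, n_draws: int = 1000, seed: int = 0) -> np.ndarray:
    """Outcome draws under the priors (no data): sanity check on support.

    Returns abs-change draws (positive) for ``"change_lognormal"`` or tau
    draws (in (0,1)) for ``"tau_mixture"``, using a single generic
    observation at sensitivity_z = 0 in an average country.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, n_draws)
    u = np.abs(rng.normal(0, 1, n_draws)) * rng.normal(0, 1, n_draws)
    eta = a + u
    if model == "change_lognormal":
        sigma = np.abs(rng.normal(0, 1, n_draws))
        return np.exp(rng.normal(eta, sigma))
    if model == "tau_mixture":
        l1 = rng.normal(0, 1.5, n_draws)
        gap = np.exp(rng.normal(0, 1, n_draws))
        phi1 = rng.gamma(2.0, 10.0, n_draws)
        phi2 = rng.gamma(2.0, 10.0, n_draws)
        mu = np.where(rng.random(n_draws) < expit(eta), expit(l1 + gap), expit(l1))
        phi = np.where(rng.random(n_draws) < 0.5, phi1, phi2)
        tau = rng.beta(mu * phi, (1 - mu) * phi)
        # same open-interval convention as the likelihood's boundary adjustment
        return _adjust_boundaries(tau)[0]
    raise ValueError(f"unknown model {model!r}")
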