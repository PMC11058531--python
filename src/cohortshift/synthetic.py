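"""Synthetic repeated cross-sectional opinion data and sensitivity-rating surveys.

Real studies of cohort replacement rely on repeated cross-sectional surveys
such as the World Values Survey: every few years a fresh sample answers the
same items, so individuals cannot be followed, but birth cohorts can.  This
module generates data of exactly that shape under three idealised regimes of
aggregate change:

``settled``
    Cohorts differ in their settled opinion levels but never change after
    their formative years; all aggregate drift comes from younger cohorts
    replacing older ones (pure between-cohort differences).
``mixed``
    Cohorts differ *and* every cohort drifts linearly over time
    (between-cohort differences plus within-cohort change).
``within_only``
    All cohorts share one starting level and one common linear trend; there
    are no between-cohort differences at all.

It also generates a respondent-level item-sensitivity survey: each synthetic
respondent rates every item on a 1-10 "how difficult to discuss" scale around
a country-level latent sensitivity, with binomial attention-check failures,
emulating the preprocessing a real crowdsourced rating survey needs.

All generators are deterministic given an explicit seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RegimeConfig",
    "SensitivitySurveyConfig",
    "JointStudyConfig",
    "ItemSpec",
    "generate_opinion_data",
    "generate_sensitivity_survey",
    "generate_joint_study",
    "settled_reference",
    "mixed_reference",
    "within_only_reference",
]

OPINION_COLUMNS = ["country", "survey_year", "birth_year", "item", "response"]
RATING_COLUMNS = ["respondent_id", "country", "item", "rating", "n_checks_missed"]


class ConfigurationError(ValueError):
    """A generator configuration violates its invariants."""


@dataclass(frozen=True)
class RegimeConfig:
    """Generative parameters for one item's cohort-structured opinion process.

    Each of ``n_cohorts`` birth cohorts (``cohort_width_years`` birth years
    wide, oldest first) has a settled opinion level ``cohort_intercepts[k]``
    and a linear per-year drift ``within_cohort_slopes[k]``.  A respondent
    from cohort ``k`` surveyed in year ``t`` answers

        response ~ Normal(intercept_k + slope_k * (t - reference_year), noise_sd)

    where ``reference_year`` is the midpoint of ``[first_year, last_year]``,
    so intercepts are period-centred.  Responses are optionally clipped to
    ``response_bounds`` and optionally rounded to integers (``discretise``)
    to emulate 10-point justifiability scales.

    Cohorts enter observation once their youngest member is at least
    ``min_age`` at the survey year; there is no mortality process.
    """

    regime_kind: str  # "settled" | "mixed" | "within_only"
    n_cohorts: int = 5
    cohort_intercepts: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    within_cohort_slopes: tuple[float, ...] = (0.0,) * 5
    noise_sd: float = 1.0
    first_year: int = 1981
    last_year: int = 2020
    n_waves: int = 8
    n_per_cohort_wave: int = 100
    cohort_width_years: int = 10
    first_cohort_birth_year: int = 1930
    min_age: int = 18
    response_bounds: tuple[float, float] | None = None
    discretise: bool = False

    def __post_init__(self) -> None:
        if self.regime_kind not in ("settled", "mixed", "within_only"):
            raise ConfigurationError(f"unknown regime_kind {self.regime_kind!r}")
        if len(self.cohort_intercepts) != self.n_cohorts:
            raise ConfigurationError(
                f"cohort_intercepts has length {len(self.cohort_intercepts)}, "
                f"expected n_cohorts={self.n_cohorts}"
            )
        if len(self.within_cohort_slopes) != self.n_cohorts:
            raise ConfigurationError(
                f"within_cohort_slopes has length {len(self.within_cohort_slopes)}, "
                f"expected n_cohorts={self.n_cohorts}"
            )
        if self.n_waves < 2:
            raise ConfigurationError("n_waves must be >= 2 (tau needs at least two years)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.n_per_cohort_wave < 1 or self.cohort_width_years < 1:
            raise ConfigurationError("n_per_cohort_wave and cohort_width_years must be positive")
        if self.last_year - self.first_year + 1 < self.n_waves:
            raise ConfigurationError("n_waves survey years do not fit in [first_year, last_year]")
        slopes = np.asarray(self.within_cohort_slopes, dtype=float)
        if self.regime_kind == "settled" and np.any(slopes != 0.0):
            raise ConfigurationError("settled regime requires all within_cohort_slopes == 0")
        if self.regime_kind == "within_only":
            icepts = np.asarray(self.cohort_intercepts, dtype=float)
            if np.ptp(icepts) != 0.0:
                raise ConfigurationError("within_only regime requires equal cohort_intercepts")
            if np.ptp(slopes) != 0.0 or slopes[0] == 0.0:
                raise ConfigurationError(
                    "within_only regime requires identical nonzero within_cohort_slopes"
                )
        if self.response_bounds is not None and self.response_bounds[0] >= self.response_bounds[1]:
            raise ConfigurationError("response_bounds must satisfy lo < hi")

    @property
    def reference_year(self) -> float:
        return (self.first_year + self.last_year) / 2.0

    @property
    def wave_years(self) -> np.ndarray:
        years = np.unique(
            np.round(np.linspace(self.first_year, self.last_year, self.n_waves)).astype(int)
        )
        return years

    def cohort_birth_window(self, k: int) -> tuple[int, int]:
        """Half-open birth-year window [start, start + width) of cohort ``k``."""
        start = self.first_cohort_birth_year + k * self.cohort_width_years
        return start, start + self.cohort_width_years


@dataclass(frozen=True)
class SensitivitySurveyConfig:
    """Parameters for the synthetic "difficulty to discuss" rating survey.

    ``latent_item_sensitivity`` maps item id -> country-level latent
    sensitivity on the 1-10 scale.  Each respondent rates every item as
    ``round(latent + Normal(0, rating_noise_sd))`` clipped to [1, 10], and
    misses ``Binomial(n_attention_checks, p_miss_check)`` attention checks.
    """

    n_respondents_per_country: int = 100
    latent_item_sensitivity: dict[str, float] = field(default_factory=dict)
    rating_noise_sd: float = 1.5
    n_attention_checks: int = 4
    # per-check miss rate such that ~0.7% of respondents fail more than two
    # of four checks, the exclusion rate typical of attentive online panels
    p_miss_check: float = 0.125

    def __post_init__(self) -> None:
        if self.n_respondents_per_country < 1:
            raise ConfigurationError("n_respondents_per_country must be positive")
        for item, s in self.latent_item_sensitivity.items():
            if not 1.0 <= s <= 10.0:
                raise ConfigurationError(f"latent sensitivity for {item!r} outside [1, 10]: {s}")
        if self.rating_noise_sd < 0:
            raise ConfigurationError("rating_noise_sd must be non-negative")
        if not 0.0 <= self.p_miss_check <= 1.0:
            raise ConfigurationError("p_miss_check must be a probability")
        if self.n_attention_checks < 0:
            raise ConfigurationError("n_attention_checks must be >= 0")


@dataclass(frozen=True)
class ItemSpec:
    """One item of a joint study: its latent sensitivity per country scale."""

    item: str
    latent_sensitivity: float


@dataclass(frozen=True)
class JointStudyConfig:
    """End-to-end study: opinions plus ratings with a known sensitivity->regime link.

    Each item x country pair is assigned the ``settled`` regime with
    probability ``logit^-1(mixing_effect * z)`` where ``z`` is the item's
    latent sensitivity standardised across items, and otherwise a ``mixed``
    regime with a common nonzero within-cohort slope.  The emitted truth
    table records the regime and generative parameters for recovery tests.
    """

    items: tuple[ItemSpec, ...]
    countries: tuple[str, ...]
    mixing_effect: float = 0.0
    seed: int = 0
    settled_template: RegimeConfig | None = None
    mixed_template: RegimeConfig | None = None
    survey: SensitivitySurveyConfig | None = None
    country_sensitivity_jitter_sd: float = 0.5

    def __post_init__(self) -> None:
        if not self.items:
            raise ConfigurationError("joint study needs at least one item")
        if not self.countries:
            raise ConfigurationError("joint study needs at least one country")


# ---------------------------------------------------------------------------
# reference regimes
# ---------------------------------------------------------------------------

def settled_reference(**overrides) -> RegimeConfig:
    """Settled-dispositions reference: 5 cohorts spanning 2 noise SDs, no drift."""
    cfg = RegimeConfig(
        regime_kind="settled",
        cohort_intercepts=(0.0, 0.5, 1.0, 1.5, 2.0),
        within_cohort_slopes=(0.0,) * 5,
        noise_sd=1.0,
    )
    return replace(cfg, **overrides) if overrides else cfg


def mixed_reference(**overrides) -> RegimeConfig:
    """Mixed reference: a 1-noise-SD cohort spread plus a common 0.05/yr drift."""
    cfg = RegimeConfig(
        regime_kind="mixed",
        cohort_intercepts=(0.0, 0.25, 0.5, 0.75, 1.0),
        within_cohort_slopes=(0.05,) * 5,
        noise_sd=1.0,
    )
    return replace(cfg, **overrides) if overrides else cfg


def within_only_reference(**overrides) -> RegimeConfig:
    """Within-change-only reference: equal intercepts, common 0.05/yr drift."""
    cfg = RegimeConfig(
        regime_kind="within_only",
        cohort_intercepts=(1.0,) * 5,
        within_cohort_slopes=(0.05,) * 5,
        noise_sd=1.0,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_opinion_data(
    config: RegimeConfig, country: str, item: str, seed: int
) -> pd.DataFrame:
    """Draw one item's repeated cross-sectional responses for one country.

    For every wave year and every cohort observable in that wave (youngest
    member at least ``config.min_age``), draws ``config.n_per_cohort_wave``
    responses around the cohort's linear trajectory.  Birth years are uniform
    within the cohort window.  Returns a long-format frame with columns
    ``country, survey_year, birth_year, item, response``.
    """
    rng = np.random.default_rng(seed)
    years = config.wave_years
    ref = config.reference_year
    rows_year: list[np.ndarray] = []
    rows_birth: list[np.ndarray] = []
    rows_resp: list[np.ndarray] = []
    n = config.n_per_cohort_wave
    for k in range(config.n_cohorts):
        b_lo, b_hi = config.cohort_birth_window(k)
        youngest = b_hi - 1
        for t in years:
            if t - youngest < config.min_age:
                continue  # cohort not yet observable in this wave
            mean = config.cohort_intercepts[k] + config.within_cohort_slopes[k] * (t - ref)
            resp = mean + rng.normal(0.0, config.noise_sd, size=n)
            births = rng.integers(b_lo, b_hi, size=n)
            rows_year.append(np.full(n, t))
            rows_birth.append(births)
            rows_resp.append(resp)
    if not rows_year:
        raise ConfigurationError(
            "no cohort is observable in any wave; check first_cohort_birth_year/min_age"
        )
    response = np.concatenate(rows_resp)
    if config.response_bounds is not None:
        response = np.clip(response, *config.response_bounds)
    if config.discretise:
        response = np.round(response)
    out = pd.DataFrame(
        {
            "country": country,
            "survey_year": np.concatenate(rows_year).astype(int),
            "birth_year": np.concatenate(rows_birth).astype(int),
            "item": item,
            "response": response,
        }
    )
    return out


def generate_sensitivity_survey(
    config: SensitivitySurveyConfig, seed: int, countries: dict[str, dict[str, float]] | None = None
) -> pd.DataFrame:
    """Draw the respondent-level difficulty-to-discuss ratings.

    ``countries`` optionally maps country -> {item -> latent sensitivity};
    when omitted a single country ``"XX"`` uses ``config.latent_item_sensitivity``.
    Each respondent rates every item; ratings are integers in 1..10.
    """
    if countries is None:
        if not config.latent_item_sensitivity:
            raise ConfigurationError("latent_item_sensitivity map is empty")
        countries = {"XX": dict(config.latent_item_sensitivity)}
    for cmap in countries.values():
        if not cmap:
            raise ConfigurationError("latent_item_sensitivity map is empty")
    rng = np.random.default_rng(seed)
    frames = []
    for country in countries:
        items = sorted(countries[country])
        latents = np.array([countries[country][it] for it in items])
        n_resp = config.n_respondents_per_country
        noise = rng.normal(0.0, config.rating_noise_sd, size=(n_resp, len(items)))
        ratings = np.clip(np.round(latents[None, :] + noise), 1, 10).astype(int)
        missed = rng.binomial(config.n_attention_checks, config.p_miss_check, size=n_resp)
        rid = np.array([f"{country}-{i:04d}" for i in range(n_resp)])
        frames.append(
            pd.DataFrame(
                {
                    "respondent_id": np.repeat(rid, len(items)),
                    "country": country,
                    "item": np.tile(items, n_resp),
                    "rating": ratings.ravel(),
                    "n_checks_missed": np.repeat(missed, len(items)),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_joint_study(
    config: JointStudyConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (opinion table, rating table, truth table) with known coupling.

    The truth table has one row per item x country with the drawn regime,
    the country-level latent sensitivity, its cross-item standardised value,
    and the generative slope, enabling parameter-recovery tests downstream.
    """
    rng = np.random.default_rng(config.seed)
    settled = config.settled_template or settled_reference()
    mixed = config.mixed_template or mixed_reference()
    survey = config.survey or SensitivitySurveyConfig()

    base = np.array([spec.latent_sensitivity for spec in config.items], dtype=float)
    # country-level latent sensitivities: item base value plus country jitter
    latent = {}
    for country in config.countries:
        jit = rng.normal(0.0, config.country_sensitivity_jitter_sd, size=len(base))
        latent[country] = np.clip(base + jit, 1.0, 10.0)
    pooled = np.concatenate([latent[c] for c in config.countries])
    mu, sd = pooled.mean(), pooled.std(ddof=0)
    if sd == 0:
        raise ConfigurationError("latent sensitivities are constant; cannot standardise")

    opinion_frames, truth_rows = [], []
    for country in config.countries:
        for j, spec in enumerate(config.items):
            z = (latent[country][j] - mu) / sd
            p_settled = 1.0 / (1.0 + np.exp(-config.mixing_effect * z))
            is_settled = rng.random() < p_settled
            regime = settled if is_settled else mixed
            sub_seed = int(rng.integers(0, 2**31 - 1))
            opinion_frames.append(
                generate_opinion_data(regime, country=country, item=spec.item, seed=sub_seed)
            )
            truth_rows.append(
                {
                    "item": spec.item,
                    "country": country,
                    "regime": "settled" if is_settled else mixed.regime_kind,
                    "latent_sensitivity": latent[country][j],
                    "sensitivity_z": z,
                    "p_settled": p_settled,
                    "within_slope": 0.0 if is_settled else mixed.within_cohort_slopes[0],
                    "intercept_spread": float(np.ptp(regime.cohort_intercepts)),
                }
            )

    rating_maps = {
        country: {spec.item: latent[country][j] for j, spec in enumerate(config.items)}
        for country in config.countries
    }
    rating_seed = int(rng.integers(0, 2**31 - 1))
    ratings = generate_sensitivity_survey(survey, seed=rating_seed, countries=rating_maps)

    opinions = pd.concat(opinion_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return opinions, ratings, truth


def to_csv_bytes(frame: pd.DataFrame) -> bytes:
    """Serialise a table exactly as the pipeline writes it (for determinism checks)."""
    buf = io.StringIO()
    frame.to_csv(buf, index=False)
    return buf.getvalue().encode()
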