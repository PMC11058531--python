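"""Nested cohort models, the tau statistic, and pooled-SD absolute change.

The decomposition at the heart of the package compares two ordinary least
squares fits to one item's responses in one country:

* **Model 1** regresses the response on birth-cohort indicators only — each
  respondent is predicted by their cohort's mean, the settled-dispositions
  limit in which people never change after their formative years.
* **Model 2** adds a linear survey-year term and a cohort x year interaction,
  i.e. each cohort follows its own linear trend over time (age and period
  effects pooled into one within-cohort drift).

Because Model 1 is nested in Model 2, R2_full >= R2_cohort_only, and

    tau = R2_cohort_only / R2_full

is the share of explainable linear change preserved when within-cohort
change is forced to zero: tau near 1 means cohort replacement alone accounts
for the trend, tau near 0 means nearly all linear change happens within
cohorts.  tau is undefined (flagged, not zero) when Model 2 explains
essentially nothing — there is then no linear structure to decompose.

Aggregate change is summarised as |mean(last wave) - mean(first wave)|
divided by the sample SD of the pooled first+last wave responses, a
scale-free effect size invariant to affine rescaling of the response scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CohortAssignment",
    "TauResult",
    "ChangeResult",
    "assign_cohorts",
    "fit_cohort_model",
    "fit_cohort_year_model",
    "compute_tau",
    "compute_abs_change",
    "summarise_items",
    "DegenerateOutcomeError",
    "InsufficientDataError",
    "CHANGE_LABEL_THRESHOLD",
]

#: pooled-SD change above which an item is flagged for plot labelling
CHANGE_LABEL_THRESHOLD = 0.8

#: cohorts with fewer observations than this are merged into a neighbour
MIN_COHORT_CELL = 5

#: Model-2 R2 below which tau is flagged undefined
TAU_EPSILON = 1e-6


class DegenerateOutcomeError(ValueError):
    """The outcome has no variance (or pooled SD is zero)."""


class InsufficientDataError(ValueError):
    """Too few cohorts, years or observations for the requested fit."""


@dataclass(frozen=True)
class CohortAssignment:
    """Deterministic half-open binning of birth years into cohorts.

    Cohort ``k`` covers birth years ``[origin + k*width, origin + (k+1)*width)``.
    """

    bin_width_years: int
    origin_year: int
    labels: dict[int, int]
    counts: dict[int, int] = field(default_factory=dict)

    def codes(self, birth_years) -> np.ndarray:
        by = np.asarray(birth_years, dtype=int)
        return (by - self.origin_year) // self.bin_width_years


def assign_cohorts(
    birth_years, bin_width_years: int = 5, origin_year: int | None = None
) -> CohortAssignment:
    """Bin birth years into contiguous half-open cohorts of fixed width.

    ``origin_year`` defaults to the earliest birth year rounded down to a
    multiple of ``bin_width_years`` (so default bins land on calendar-round
    boundaries such as 1950-54, 1955-59).
    """
    by = np.asarray(birth_years, dtype=int)
    if by.size == 0:
        raise InsufficientDataError("no birth years to assign")
    if bin_width_years < 1:
        raise ValueError("bin_width_years must be >= 1")
    if origin_year is None:
        origin_year = int(by.min() // bin_width_years * bin_width_years)
    codes = (by - origin_year) // bin_width_years
    labels = {int(b): int(c) for b, c in zip(by, codes)}
    uniq, cnt = np.unique(codes, return_counts=True)
    counts = {int(u): int(c) for u, c in zip(uniq, cnt)}
    return CohortAssignment(bin_width_years, int(origin_year), labels, counts)


def _merge_sparse_cohorts(codes: np.ndarray, min_cell: int = MIN_COHORT_CELL) -> np.ndarray:
    """Merge cohorts with < min_cell observations into the nearest neighbour.

    Prevents rank-deficiency in the interaction model.  Merging is iterative
    (a merged pair may still be sparse) and deterministic: the sparse cohort
    joins whichever adjacent surviving cohort is nearest in code, ties going
    to the older (smaller-code) cohort.
    """
    codes = codes.copy()
    while True:
        uniq, cnt = np.unique(codes, return_counts=True)
        if len(uniq) <= 1:
            return codes
        sparse = uniq[cnt < min_cell]
        if sparse.size == 0:
            return codes
        s = sparse[0]
        others = uniq[uniq != s]
        target = others[np.argmin(np.abs(others - s))]
        logger.warning("merging sparse cohort %d (n=%d) into cohort %d", s, cnt[uniq == s][0], target)
        codes[codes == s] = target


def _r2(y: np.ndarray, fitted: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise DegenerateOutcomeError("outcome variance is zero")
    ssr = float(np.sum((y - fitted) ** 2))
    return 1.0 - ssr / sst


def _prepare(records: pd.DataFrame, assignment: CohortAssignment, merge_sparse: bool):
    y = records["response"].to_numpy(dtype=float)
    codes = assignment.codes(records["birth_year"].to_numpy())
    if merge_sparse:
        codes = _merge_sparse_cohorts(codes)
    return y, codes


def fit_cohort_model(
    records: pd.DataFrame, assignment: CohortAssignment, merge_sparse: bool = True
) -> tuple[np.ndarray, float]:
    """Model 1: response on cohort indicators; fitted values are cohort means."""
    y, codes = _prepare(records, assignment, merge_sparse)
    if len(np.unique(codes)) < 2:
        warnings.warn("single cohort: cohort-only model reduces to the grand mean (R2 = 0)")
        # intercept-only fit explains nothing
        _ = _r2(y, np.full_like(y, y.mean()))  # still raises on zero variance
        return np.full_like(y, y.mean()), 0.0
    fitted = np.empty_like(y)
    for c in np.unique(codes):
        m = codes == c
        fitted[m] = y[m].mean()
    return fitted, _r2(y, fitted)


def fit_cohort_year_model(
    records: pd.DataFrame, assignment: CohortAssignment, merge_sparse: bool = True
) -> tuple[np.ndarray, float]:
    """Model 2: cohort indicators + centred linear year + cohort x year.

    The full interaction design spans exactly one straight line in survey
    year per cohort, so the least-squares fit is computed as a separate
    simple linear regression within each cohort.  A cohort observed in a
    single survey year is rank-deficient in the interaction; its trend term
    is dropped (fitted value = its cell mean) with a logged warning.
    """
    y, codes = _prepare(records, assignment, merge_sparse)
    years = records["survey_year"].to_numpy(dtype=float)
    if len(np.unique(years)) < 2:
        raise InsufficientDataError(
            "a single survey year cannot identify within-cohort change; fit Model 1 only"
        )
    t = years - years.mean()  # centring leaves fitted values and R2 unchanged
    fitted = np.empty_like(y)
    for c in np.unique(codes):
        m = codes == c
        tc, yc = t[m], y[m]
        if len(np.unique(tc)) < 2:
            logger.warning("cohort %d observed in one survey year; interaction dropped", c)
            fitted[m] = yc.mean()
            continue
        slope, intercept = np.polyfit(tc, yc, 1)
        fitted[m] = intercept + slope * tc
    return fitted, _r2(y, fitted)


@dataclass(frozen=True)
class TauResult:
    """Per item x country variance-decomposition summary."""

    item: str
    country: str
    r2_cohort_only: float
    r2_full: float
    tau: float | None
    tau_defined: bool
    n_obs: int
    n_cohorts_used: int


@dataclass(frozen=True)
class ChangeResult:
    """Per item x country absolute change between first and last waves."""

    item: str
    country: str
    abs_change_sd: float
    first_year: int
    last_year: int


def compute_tau(
    records: pd.DataFrame,
    assignment: CohortAssignment,
    item: str = "",
    country: str = "",
    epsilon: float = TAU_EPSILON,
) -> TauResult:
    """Fit both nested models and form tau = R2_cohort_only / R2_full.

    tau is flagged undefined (``tau=None``) when R2_full < ``epsilon``:
    an item with no linear structure offers nothing to decompose.
    """
    _, codes = _prepare(records, assignment, merge_sparse=True)
    _, r2_1 = fit_cohort_model(records, assignment)
    _, r2_2 = fit_cohort_year_model(records, assignment)
    # nested OLS guarantees r2_2 >= r2_1 up to floating point noise
    if r2_2 < r2_1:
        if r2_1 - r2_2 > 1e-8:
            raise AssertionError(f"nesting violated: R2_full={r2_2} < R2_cohort={r2_1}")
        r2_2 = r2_1
    defined = r2_2 >= epsilon
    tau = min(r2_1 / r2_2, 1.0) if defined else None
    return TauResult(
        item=item,
        country=country,
        r2_cohort_only=r2_1,
        r2_full=r2_2,
        tau=tau,
        tau_defined=defined,
        n_obs=len(records),
        n_cohorts_used=len(np.unique(codes)),
    )


def compute_abs_change(
    records: pd.DataFrame, item: str = "", country: str = ""
) -> ChangeResult:
    """|last-wave mean - first-wave mean| in pooled first+last wave SD units."""
    years = records["survey_year"].to_numpy()
    uniq = np.unique(years)
    if uniq.size < 2:
        raise InsufficientDataError("need at least two survey years to measure change")
    first, last = uniq[0], uniq[-1]
    y_first = records.loc[records["survey_year"] == first, "response"].to_numpy(dtype=float)
    y_last = records.loc[records["survey_year"] == last, "response"].to_numpy(dtype=float)
    pooled = np.concatenate([y_first, y_last])
    sd = float(np.std(pooled, ddof=1))
    if sd == 0.0:
        raise DegenerateOutcomeError("pooled first+last wave SD is zero")
    return ChangeResult(
        item=item,
        country=country,
        abs_change_sd=abs(float(y_last.mean() - y_first.mean())) / sd,
        first_year=int(first),
        last_year=int(last),
    )


def summarise_items(
    opinions: pd.DataFrame,
    bin_width_years: int = 5,
    epsilon: float = TAU_EPSILON,
    change_label_threshold: float = CHANGE_LABEL_THRESHOLD,
) -> pd.DataFrame:
    """Compute tau and absolute change for every item x country.

    Returns one row per item x country with columns
    ``item, country, r2_cohort_only, r2_full, tau, tau_defined, abs_change_sd,
    first_year, last_year, n_obs, n_cohorts_used, bin_width, label_change``.
    Rows with undefined tau are retained and flagged; items that fail
    (degenerate outcome, single wave) are logged and omitted.
    """
    required = {"country", "survey_year", "birth_year", "item", "response"}
    missing = required - set(opinions.columns)
    if missing:
        raise ValueError(f"opinion table is missing columns: {sorted(missing)}")
    rows = []
    for (item, country), grp in opinions.groupby(["item", "country"], sort=True):
        if grp.empty:
            continue
        try:
            assignment = assign_cohorts(grp["birth_year"].to_numpy(), bin_width_years)
            tau_res = compute_tau(grp, assignment, item=item, country=country, epsilon=epsilon)
            chg = compute_abs_change(grp, item=item, country=country)
        except (DegenerateOutcomeError, InsufficientDataError) as exc:
            logger.warning("skipping %s/%s: %s", item, country, exc)
            continue
        rows.append(
            {
                "item": item,
                "country": country,
                "r2_cohort_only": tau_res.r2_cohort_only,
                "r2_full": tau_res.r2_full,
                "tau": np.nan if tau_res.tau is None else tau_res.tau,
                "tau_defined": tau_res.tau_defined,
                "abs_change_sd": chg.abs_change_sd,
                "first_year": chg.first_year,
                "last_year": chg.last_year,
                "n_obs": tau_res.n_obs,
                "n_cohorts_used": tau_res.n_cohorts_used,
                "bin_width": bin_width_years,
                "label_change": chg.abs_change_sd > change_label_threshold,
            }
        )
    return pd.DataFrame(rows)
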