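"""Respondent-level difficulty ratings -> per-item, per-country sensitivity scores.

Respondents rate, on a 1-10 scale ("not difficult at all" to "extremely
difficult"), how hard it would be for the majority of their compatriots to
discuss each survey question.  Respondents who miss more than two attention
checks are excluded; surviving ratings are aggregated per item and country
by the median (robust to extreme raters; the mean is kept alongside as a
robustness column) and standardised to z-scores for use as the predictor in
the hierarchical models.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "apply_attention_filter",
    "aggregate_item_sensitivity",
    "standardise_sensitivity",
    "top_items_by_country",
]

#: respondents missing more than this many attention checks are dropped
MAX_MISSED_CHECKS = 2


def apply_attention_filter(ratings: pd.DataFrame, max_missed: int = MAX_MISSED_CHECKS) -> pd.DataFrame:
    """Drop respondents who missed more than ``max_missed`` attention checks.

    Operates on the long rating table (``respondent_id, country, item,
    rating, n_checks_missed``); a respondent is kept iff
    ``n_checks_missed <= max_missed``.  Idempotent.  Logs respondent counts
    before and after.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if "n_checks_missed" not in ratings.columns:
        raise ValueError("rating table lacks the n_checks_missed column")
    n_before = ratings["respondent_id"].nunique()
    kept = ratings.loc[ratings["n_checks_missed"] <= max_missed].reset_index(drop=True)
    n_after = kept["respondent_id"].nunique()
    logger.info("attention filter: %d -> %d respondents", n_before, n_after)
    return kept


def aggregate_item_sensitivity(ratings: pd.DataFrame) -> pd.DataFrame:
    """Median (and mean) rating per item x country over retained raters.

    Returns columns ``item, country, n_raters, median_rating, mean_rating``.
    Item x country cells with zero raters are simply absent.
    """
    if ratings.empty:
        logger.warning("no ratings to aggregate")
        return pd.DataFrame(columns=["item", "country", "n_raters", "median_rating", "mean_rating"])
    agg = (
        ratings.groupby(["item", "country"], sort=True)["rating"]
        .agg(n_raters="size", median_rating="median", mean_rating="mean")
        .reset_index()
    )
    return agg


def standardise_sensitivity(
    items: pd.DataFrame, pool: str = "global", column: str = "median_rating"
) -> pd.DataFrame:
    """Attach z-scored sensitivity: (rating - pool mean) / pool SD.

    ``pool`` is ``"global"`` (all item x country cells share one scale, the
    default, matching models that put every country on a common sensitivity
    axis) or ``"per_country"``.  SD uses ddof=0 so the scores have sample
    mean 0 and SD 1 exactly over their pool.
    """
    if pool not in ("global", "per_country"):
        raise ValueError(f"unknown pool {pool!r}")
    out = items.copy()
    if len(out) < 2:
        raise ValueError("need at least two items to standardise")

    def _z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError("zero SD in standardisation pool")
        return (x - x.mean()) / sd

    if pool == "global":
        out["sensitivity_z"] = _z(out[column])
    else:
        out["sensitivity_z"] = out.groupby("country", group_keys=False)[column].apply(_z)
    return out


def top_items_by_country(items: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """The k most sensitive items per country by median rating (ties by item id)."""
    return (
        items.sort_values(["country", "median_rating", "item"], ascending=[True, False, True])
        .groupby("country", sort=True)
        .head(k)
        .reset_index(drop=True)
    )
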