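"""End-to-end study orchestration: generate -> summarise -> model -> report.

A run takes long-format opinion data and respondent-level sensitivity
ratings (either synthetic, generated under a configured coupling between
sensitivity and change regime, or loaded from CSV), computes the per
item x country tau and pooled-SD change table, aggregates sensitivity
scores, fits the three hierarchical models, and writes a reproducible
bundle: CSV summaries, prediction curves, a diagnostics JSON, figures, and
an echo of the exact configuration used.  All randomness flows from the
single seed in the configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import core, hier, sensitivity, synthetic

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_study",
    "make_default_study",
    "load_config",
    "plot_tau_vs_change",
    "plot_prediction_curves",
]

#: the eight countries of the default study design
DEFAULT_COUNTRIES = ("AR", "AU", "CA", "JP", "MX", "SE", "US", "ZA")


@dataclass(frozen=True)
class RunConfig:
    """Fully serialisable description of one pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "csv"
    opinion_csv: str | None = None
    rating_csv: str | None = None
    outdir: str = "cohortshift_run"
    seed: int = 0
    # synthetic-study design
    n_items: int = 56
    countries: tuple[str, ...] = DEFAULT_COUNTRIES
    mixing_effect: float = 0.0
    n_per_cohort_wave: int = 100
    n_respondents_per_country: int = 100
    # analysis settings
    bin_width_years: int = 5
    epsilon: float = core.TAU_EPSILON
    change_zero_handling: str = "drop"
    sampler: dict = field(default_factory=dict)
    make_figures: bool = True

    def sampler_settings(self) -> hier.SamplerSettings:
        return hier.SamplerSettings(seed=self.seed, **self.sampler)


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML (unknown keys are an error)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "countries" in raw:
        raw["countries"] = tuple(raw["countries"])
    return RunConfig(**raw)


def make_default_study(
    mixing_effect: float = 0.0,
    seed: int = 0,
    n_items: int = 56,
    countries: tuple[str, ...] = DEFAULT_COUNTRIES,
    n_per_cohort_wave: int = 100,
    n_respondents_per_country: int = 100,
) -> synthetic.JointStudyConfig:
    """Default joint-study design: items span the 1-10 sensitivity scale evenly."""
    latents = np.linspace(2.0, 9.0, n_items)
    items = tuple(
        synthetic.ItemSpec(item=f"item{i + 1:02d}", latent_sensitivity=float(s))
        for i, s in enumerate(latents)
    )
    survey = synthetic.SensitivitySurveyConfig(
        n_respondents_per_country=n_respondents_per_country
    )
    settled = synthetic.settled_reference(n_per_cohort_wave=n_per_cohort_wave)
    mixed = synthetic.mixed_reference(n_per_cohort_wave=n_per_cohort_wave)
    return synthetic.JointStudyConfig(
        items=items,
        countries=tuple(countries),
        mixing_effect=mixing_effect,
        seed=seed,
        settled_template=settled,
        mixed_template=mixed,
        survey=survey,
    )


def _load_inputs(config: RunConfig, outdir: Path):
    if config.mode == "synthetic":
        study = make_default_study(
            mixing_effect=config.mixing_effect,
            seed=config.seed,
            n_items=config.n_items,
            countries=config.countries,
            n_per_cohort_wave=config.n_per_cohort_wave,
            n_respondents_per_country=config.n_respondents_per_country,
        )
        opinions, ratings, truth = synthetic.generate_joint_study(study)
        truth.to_csv(outdir / "truth_table.csv", index=False)
        opinions.to_csv(outdir / "opinions.csv", index=False)
        ratings.to_csv(outdir / "ratings.csv", index=False)
        return opinions, ratings
    if config.mode != "csv":
        raise ValueError(f"unknown mode {config.mode!r}")
    if not config.opinion_csv or not config.rating_csv:
        raise ValueError("csv mode requires opinion_csv and rating_csv paths")
    opinions = pd.read_csv(config.opinion_csv)
    ratings = pd.read_csv(config.rating_csv)
    for frame, cols, name in (
        (opinions, synthetic.OPINION_COLUMNS, "opinion"),
        (ratings, synthetic.RATING_COLUMNS, "rating"),
    ):
        missing = set(cols) - set(frame.columns)
        if missing:
            raise ValueError(f"{name} CSV is missing columns: {sorted(missing)}")
    return opinions, ratings


def summarise(opinions: pd.DataFrame, ratings: pd.DataFrame, config: RunConfig):
    """Stage 2: tau/change table and standardised sensitivity table."""
    tau_summary = core.summarise_items(
        opinions, bin_width_years=config.bin_width_years, epsilon=config.epsilon
    )
    kept = sensitivity.apply_attention_filter(ratings)
    sens = sensitivity.aggregate_item_sensitivity(kept)
    sens = sensitivity.standardise_sensitivity(sens, pool="global")
    return tau_summary, sens


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline and write the output bundle to ``config.outdir``.

    Returns a dict with the key tables, fitted model summaries, the output
    paths, and ``converged`` (False if any model failed the R-hat gate).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    )

    opinions, ratings = _load_inputs(config, outdir)
    tau_summary, sens = summarise(opinions, ratings, config)
    tau_summary.to_csv(outdir / "tau_summary.csv", index=False)
    sens.to_csv(outdir / "sensitivity_summary.csv", index=False)

    joined = tau_summary.merge(
        sens[["item", "country", "sensitivity_z", "median_rating"]],
        on=["item", "country"],
        how="inner",
    )
    if joined.empty:
        raise ValueError("tau table and sensitivity table share no item x country rows")

    settings = config.sampler_settings()
    summaries: dict[str, hier.PosteriorSummary] = {}
    summaries["change_lognormal"] = hier.fit_change_model(
        joined, settings=settings, zero_handling=config.change_zero_handling
    )
    summaries["tau_mixture"] = hier.fit_tau_mixture_model(joined, settings=settings)
    summaries["tau_gaussian"] = hier.fit_tau_gaussian_model(joined, settings=settings)

    diagnostics = {}
    for name, summ in summaries.items():
        summ.params.reset_index().to_csv(outdir / f"posterior_summary_{name}.csv", index=False)
        curves = hier.predict_curves(summ)
        curves.to_csv(outdir / f"prediction_curves_{name}.csv", index=False)
        diagnostics[name] = {**summ.diagnostics, **summ.metadata}
    (outdir / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))

    if config.make_figures:
        plot_tau_vs_change(tau_summary, outdir / "tau_vs_change.png")
        for name, summ in summaries.items():
            plot_prediction_curves(summ.curves, outdir / f"prediction_curves_{name}.png")

    converged = all(s.diagnostics["converged"] for s in summaries.values())
    if not converged:
        logger.warning("one or more models failed the R-hat convergence gate")
    return {
        "tau_summary": tau_summary,
        "sensitivity_summary": sens,
        "joined": joined,
        "models": summaries,
        "outdir": outdir,
        "converged": converged,
    }


# ---------------------------------------------------------------------------
# figures (derived views of the CSV outputs, never independent computations)
# ---------------------------------------------------------------------------

def plot_tau_vs_change(tau_summary: pd.DataFrame, path: str | Path | None = None):
    """Per-country scatter of tau against pooled-SD absolute change.

    Items changing more than the labelling threshold (0.8 SD) are annotated;
    items in the upper-right region change a lot *and* are well predicted by
    cohort replacement alone.
    """
    countries = [c for c, g in tau_summary.groupby("country") if len(g)]
    if not countries:
        logger.warning("no countries to plot")
        return None
    ncol = min(4, len(countries))
    nrow = -(-len(countries) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.0 * nrow), squeeze=False)
    for ax in axes.ravel()[len(countries):]:
        ax.set_visible(False)
    for ax, country in zip(axes.ravel(), countries):
        grp = tau_summary[tau_summary["country"] == country]
        defined = grp[grp["tau_defined"]]
        ax.scatter(defined["abs_change_sd"], defined["tau"], s=12, alpha=0.7)
        for _, row in defined[defined["label_change"]].iterrows():
            ax.annotate(row["item"], (row["abs_change_sd"], row["tau"]), fontsize=6)
        ax.axvline(core.CHANGE_LABEL_THRESHOLD, color="grey", lw=0.5, ls="--")
        ax.set_title(country, fontsize=9)
        ax.set_ylim(-0.05, 1.05)
        ax.set_xlabel("abs change (pooled SD)")
        ax.set_ylabel(r"$\tau$")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_prediction_curves(curves: pd.DataFrame, path: str | Path | None = None):
    """Per-country posterior-mean prediction lines over the sensitivity grid."""
    if curves is None or curves.empty:
        logger.warning("no prediction curves to plot")
        return None
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for country, grp in curves.groupby("country"):
        ax.plot(grp["sensitivity_z"], grp["prediction"], label=country, lw=1.2)
    ax.set_xlabel("sensitivity (SD from mean)")
    ax.set_ylabel("posterior-mean prediction")
    ax.set_title(str(curves["model"].iloc[0]))
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
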