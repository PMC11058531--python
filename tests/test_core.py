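"""Nested-model R2, tau and pooled-SD change against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cohortshift import (
    assign_cohorts,
    compute_abs_change,
    compute_tau,
    fit_cohort_model,
    fit_cohort_year_model,
    generate_opinion_data,
    mixed_reference,
    settled_reference,
    summarise_items,
    within_only_reference,
)
from cohortshift.core import DegenerateOutcomeError, InsufficientDataError


def oracle_r2(records: pd.DataFrame, codes: np.ndarray, with_year: bool) -> float:
    """Brute-force normal-equations R2 on the explicit dummy design matrix."""
    y = records["response"].to_numpy(dtype=float)
    uniq = np.unique(codes)
    cols = [(codes == c).astype(float) for c in uniq]
    if with_year:
        t = records["survey_year"].to_numpy(dtype=float)
        t = t - t.mean()
        cols += [(codes == c) * t for c in uniq]
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return 1.0 - np.sum((y - fitted) ** 2) / np.sum((y - y.mean()) ** 2)


def random_table(rng, n_rows=None):
    n = n_rows or rng.integers(6, 21)
    years = rng.choice([1990, 2000, 2010], size=n)
    births = rng.choice([1950, 1952, 1961, 1964, 1973], size=n)
    y = rng.normal(size=n)
    return pd.DataFrame(
        {"country": "XX", "survey_year": years, "birth_year": births, "item": "i", "response": y}
    )


class TestAssignCohorts:
    def test_half_open_binning_example(self):
        a = assign_cohorts([1950, 1954, 1955], bin_width_years=5, origin_year=1950)
        assert a.labels == {1950: 0, 1954: 0, 1955: 1}
        assert a.counts == {0: 2, 1: 1}

    def test_width_one_each_year_own_cohort(self):
        a = assign_cohorts([1950, 1951, 1952], bin_width_years=1)
        assert len(set(a.labels.values())) == 3

    def test_partition_exhaustive_and_disjoint(self):
        years = np.arange(1900, 2001)
        a = assign_cohorts(years, bin_width_years=10, origin_year=1900)
        codes = a.codes(years)
        # brute force: every year maps to exactly one bin and bins are contiguous
        for year, code in zip(years, codes):
            assert 1900 + 10 * code <= year < 1900 + 10 * (code + 1)
        assert len(np.unique(codes)) in (10, 11)
        assert sum(a.counts.values()) == len(years)

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            assign_cohorts([])


def _frame(births, years, y):
    return pd.DataFrame(
        {
            "country": "XX",
            "survey_year": years,
            "birth_year": births,
            "item": "i",
            "response": y,
        }
    )


class TestCohortModel:
    def test_perfect_separation_r2_one(self):
        df = _frame([1950] * 3 + [1960] * 3, [1990, 2000, 2010] * 2, [0, 0, 0, 1, 1, 1])
        a = assign_cohorts(df.birth_year, 5)
        _, r2 = fit_cohort_model(df, a, merge_sparse=False)
        assert r2 == pytest.approx(1.0)

    def test_single_cohort_r2_zero_with_warning(self):
        df = _frame([1950, 1951, 1952, 1953], [1990, 1990, 2000, 2000], [1.0, 2.0, 3.0, 4.0])
        a = assign_cohorts(df.birth_year, 5)
        with pytest.warns(UserWarning, match="single cohort"):
            _, r2 = fit_cohort_model(df, a)
        assert r2 == 0.0

    def test_hand_computed_four_row_example(self):
        # cohort A: {1, 3}, cohort B: {5, 7}: SST = 20, cohort means 2 and 6, SSR = 4
        df = _frame([1950, 1951, 1960, 1961], [1990, 2000, 1990, 2000], [1.0, 3.0, 5.0, 7.0])
        a = assign_cohorts(df.birth_year, 5)
        fitted, r2 = fit_cohort_model(df, a, merge_sparse=False)
        assert r2 == pytest.approx(16 / 20)
        assert fitted == pytest.approx([2, 2, 6, 6])

    def test_zero_variance_rejected(self):
        df = _frame([1950, 1960], [1990, 2000], [1.0, 1.0])
        a = assign_cohorts(df.birth_year, 5)
        with pytest.raises(DegenerateOutcomeError):
            fit_cohort_model(df, a, merge_sparse=False)


class TestCohortYearModel:
    def test_exact_linear_trends_r2_one(self):
        cfg = mixed_reference(noise_sd=1e-14, n_per_cohort_wave=4)
        df = generate_opinion_data(cfg, "US", "x", seed=0)
        a = assign_cohorts(df.birth_year, cfg.cohort_width_years)
        _, r2 = fit_cohort_year_model(df, a)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_single_survey_year_rejected(self):
        df = _frame([1950, 1960] * 3, [1990] * 6, [1, 2, 3, 4, 5, 6])
        a = assign_cohorts(df.birth_year, 5)
        with pytest.raises(InsufficientDataError, match="single survey year"):
            fit_cohort_year_model(df, a, merge_sparse=False)

    def test_saturated_two_by_two_matches_lstsq_oracle(self):
        df = _frame(
            [1950, 1950, 1960, 1960], [1990, 2000, 1990, 2000], [1.0, 4.0, 2.0, 8.0]
        )
        a = assign_cohorts(df.birth_year, 5)
        codes = a.codes(df.birth_year)
        fitted, r2 = fit_cohort_year_model(df, a, merge_sparse=False)
        assert r2 == pytest.approx(oracle_r2(df, codes, with_year=True), abs=1e-12)
        assert fitted == pytest.approx(df.response.to_numpy())  # saturated fit

    def test_cohort_seen_in_one_year_falls_back_to_cell_mean(self):
        df = _frame(
            [1950, 1950, 1950, 1960, 1960],
            [1990, 1990, 2000, 1990, 1990],
            [1.0, 2.0, 3.0, 4.0, 6.0],
        )
        a = assign_cohorts(df.birth_year, 5)
        fitted, r2 = fit_cohort_year_model(df, a, merge_sparse=False)
        assert fitted[3] == pytest.approx(5.0)
        assert fitted[4] == pytest.approx(5.0)
        assert 0 <= r2 <= 1

    def test_oracle_equivalence_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(12):
            df = random_table(rng)
            a = assign_cohorts(df.birth_year, 5)
            codes = a.codes(df.birth_year)
            _, r2_1 = fit_cohort_model(df, a, merge_sparse=False)
            _, r2_2 = fit_cohort_year_model(df, a, merge_sparse=False)
            assert r2_1 == pytest.approx(oracle_r2(df, codes, False), abs=1e-10)
            assert r2_2 == pytest.approx(oracle_r2(df, codes, True), abs=1e-10)


class TestTau:
    def test_identical_fits_give_tau_exactly_one(self):
        # each cohort observed in a single year: Model 2 cannot improve on Model 1
        df = _frame(
            [1950] * 5 + [1960] * 5,
            [1990] * 5 + [2000] * 5,
            [1.0, 2.0, 3.0, 2.0, 2.0, 7.0, 8.0, 9.0, 8.0, 8.0],
        )
        res = compute_tau(df, assign_cohorts(df.birth_year, 5))
        assert res.tau == 1.0

    def test_no_linear_structure_flagged_undefined(self):
        # antisymmetric cells: every cohort-year mean is zero, so R2_full = 0
        df = _frame(
            [1950, 1950, 1960, 1960] * 2,
            [1990] * 4 + [2000] * 4,
            [-1, 1, -2, 2, -1, 1, -2, 2],
        )
        res = compute_tau(df, assign_cohorts(df.birth_year, 5))
        assert not res.tau_defined
        assert res.tau is None

    def test_sparse_cohorts_merged(self):
        df = _frame(
            [1950] * 10 + [1955] * 2 + [1960] * 10,
            ([1990] * 5 + [2000] * 5) + [1990, 2000] + ([1990] * 5 + [2000] * 5),
            np.arange(22, dtype=float),
        )
        res = compute_tau(df, assign_cohorts(df.birth_year, 5))
        assert res.n_cohorts_used == 2  # middle cohort (n=2) merged away

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_nesting_invariant_random_data(self, seed):
        df = random_table(np.random.default_rng(seed), n_rows=18)
        res = compute_tau(df, assign_cohorts(df.birth_year, 5))
        assert res.r2_full >= res.r2_cohort_only
        if res.tau is not None:
            assert res.tau <= 1.0

    def test_monotone_in_within_cohort_slope(self):
        # stronger common drift leaves less variance for cohorts alone
        grid = [0.0, 0.01, 0.02, 0.04, 0.08]
        means = []
        for slope in grid:
            taus = []
            for seed in range(20):
                if slope == 0:
                    cfg = settled_reference(n_per_cohort_wave=30)
                else:
                    cfg = mixed_reference(
                        cohort_intercepts=(0.0, 0.5, 1.0, 1.5, 2.0),
                        within_cohort_slopes=(slope,) * 5,
                        n_per_cohort_wave=30,
                    )
                df = generate_opinion_data(cfg, "US", "x", seed=seed)
                taus.append(compute_tau(df, assign_cohorts(df.birth_year, 10)).tau)
            means.append(np.mean(taus))
        assert all(a >= b - 0.02 for a, b in zip(means, means[1:]))  # weakly decreasing


class TestAbsChange:
    def test_identical_waves_zero(self):
        df = _frame([1950] * 4, [1990, 1990, 2000, 2000], [1.0, 2.0, 1.0, 2.0])
        assert compute_abs_change(df).abs_change_sd == 0.0

    def test_hand_computed_pooled_sd_example(self):
        # first wave {1,1,3,3}, last {3,3,5,5}: |4-2| / sd of the pooled eight values
        df = _frame(
            [1950] * 8,
            [1990] * 4 + [2000] * 4,
            [1.0, 1.0, 3.0, 3.0, 3.0, 3.0, 5.0, 5.0],
        )
        expected = 2.0 / np.sqrt(16 / 7)  # sample SD, pooled mean 3, sum sq dev 16
        assert compute_abs_change(df).abs_change_sd == pytest.approx(expected)

    @settings(derandomize=True, max_examples=25)
    @given(
        st.floats(min_value=0.1, max_value=50, allow_nan=False),
        st.floats(min_value=-100, max_value=100, allow_nan=False),
    )
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(1)
        df = random_table(rng, n_rows=16)
        base = compute_abs_change(df).abs_change_sd
        df2 = df.assign(response=df.response * scale + shift)
        assert compute_abs_change(df2).abs_change_sd == pytest.approx(base, rel=1e-9)

    def test_middle_waves_ignored(self):
        df = _frame(
            [1950] * 6,
            [1990, 1990, 1995, 1995, 2000, 2000],
            [0.0, 2.0, 50.0, -50.0, 4.0, 6.0],
        )
        expected = compute_abs_change(df[df.survey_year != 1995]).abs_change_sd
        assert compute_abs_change(df).abs_change_sd == pytest.approx(expected)

    def test_degenerate_pooled_sd(self):
        df = _frame([1950] * 4, [1990, 1990, 2000, 2000], [2.0, 2.0, 2.0, 2.0])
        with pytest.raises(DegenerateOutcomeError):
            compute_abs_change(df)


@pytest.fixture(scope="module")
def three_regime_table():
    frames = []
    for name, ref in (
        ("settled", settled_reference),
        ("within", within_only_reference),
    ):
        for k in range(3):
            cfg = ref(n_per_cohort_wave=20)
            frames.append(generate_opinion_data(cfg, "US", f"{name}{k}", seed=k))
    return pd.concat(frames, ignore_index=True)


class TestSummariseItems:

    def test_regime_ranks_separate(self, three_regime_table):
        out = summarise_items(three_regime_table)
        out["kind"] = out["item"].str.extract(r"([a-z]+)")
        settled = out.loc[out.kind == "settled", "tau"]
        within = out.loc[out.kind == "within", "tau"]
        assert settled.min() > within.max()

    def test_label_flag_matches_threshold(self, three_regime_table):
        out = summarise_items(three_regime_table)
        assert (out.label_change == (out.abs_change_sd > 0.8)).all()

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            summarise_items(pd.DataFrame({"item": [], "country": []}))

    def test_degenerate_item_skipped_not_fatal(self):
        good = generate_opinion_data(settled_reference(n_per_cohort_wave=10), "US", "ok", 0)
        bad = _frame([1950, 1960] * 2, [1990, 1990, 2000, 2000], [1.0, 1.0, 1.0, 1.0])
        out = summarise_items(pd.concat([good, bad.assign(item="flat")], ignore_index=True))
        assert set(out.item) == {"ok"}
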