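"""Tolerance-limit withdrawal estimation: dataset construction, pooled
log-linear regression, the noncentral-t tolerance bound, crossing search,
outlier screening, rounding and the two regulatory pipelines."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flunipk.augment import AugmentationSpec
from flunipk.withdrawal import (
    DataFormatError,
    DepletionDataset,
    InsufficientDataError,
    NotCalculableError,
    ToleranceLimitFit,
    build_depletion_dataset,
    detect_outlier_animals,
    ema_sclr,
    fda_milk_discard,
    fit_depletion_regression,
    round_to_milking,
    tolerance_limit,
    withdrawal_time,
)
from conftest import make_depletion_frame

ANALYTIC_WDT = math.log(100.0 / 0.4) / 0.1155  # 47.80 h


class TestBuildDataset:
    def test_all_below_loq_is_insufficient(self):
        df = make_depletion_frame(n_animals=4, c0=0.5)  # everything < LOQ soon
        df["conc_ng_ml"] = 0.1
        with pytest.raises(InsufficientDataError):
            build_depletion_dataset(df)

    def test_record_counting(self):
        df = make_depletion_frame(n_animals=8,
                                  times=(2.0, 4.0, 6.0, 8.0, 12.0, 18.0))
        ds = build_depletion_dataset(df)
        assert ds.n_records == 48
        assert ds.n_animals == 8

    def test_value_exactly_at_loq_is_excluded(self):
        df = make_depletion_frame(n_animals=3, times=(2.0, 4.0, 6.0))
        # a post-peak value exactly at the LOQ: "greater than" is strict
        idx = df.index[(df["animal_id"] == "goat-01") & (df["time_h"] == 6.0)]
        df.loc[idx, "conc_ng_ml"] = 0.9
        ds = build_depletion_dataset(df, loq=0.9)
        assert ds.n_records == 8
        assert ds.exclusions["at_or_below_loq"] == 1

    def test_pre_peak_points_dropped(self):
        rows = []
        for a in range(3):
            for t, c in [(1.0, 50.0), (2.0, 80.0), (4.0, 60.0), (8.0, 40.0)]:
                rows.append({"animal_id": f"g{a}", "time_h": t, "conc_ng_ml": c})
        ds = build_depletion_dataset(pd.DataFrame(rows))
        assert ds.exclusions["pre_peak"] == 3
        assert (ds.records.groupby("animal_id")["time_h"].min() == 2.0).all()


class TestRegression:
    def test_exact_log_linear_fit(self):
        ds = build_depletion_dataset(make_depletion_frame(n_animals=8))
        fit = fit_depletion_regression(ds)
        assert fit.intercept == pytest.approx(math.log(100.0), abs=1e-9)
        assert fit.slope == pytest.approx(-0.1155, abs=1e-9)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)
        assert fit.slope_p_one_sided == 0.0

    def test_slope_estimate_is_unbiased(self):
        rng = np.random.default_rng(12)
        slopes = []
        for _ in range(2000):
            t = np.tile([2.0, 4.0, 8.0, 12.0, 18.0, 24.0], 10)  # n = 60
            y = math.log(100.0) - 0.1155 * t + rng.normal(0, 0.15, t.size)
            b = stats.linregress(t, y).slope
            slopes.append(b)
        assert np.mean(slopes) == pytest.approx(-0.1155, rel=0.01)
        # and the package regression agrees with the oracle on one draw
        rng2 = np.random.default_rng(12)
        df = make_depletion_frame(n_animals=10, resid_sd=0.15, rng=rng2)
        ds = build_depletion_dataset(df)
        fit = fit_depletion_regression(ds)
        t = ds.records["time_h"].to_numpy()
        y = ds.records["ln_conc"].to_numpy()
        assert fit.slope == pytest.approx(stats.linregress(t, y).slope,
                                          rel=1e-12)

    def test_per_animal_mean_mode_collapses_replicates(self):
        rng = np.random.default_rng(20)
        df = make_depletion_frame(n_animals=6, resid_sd=0.1, rng=rng)
        ds = build_depletion_dataset(df)
        reps = pd.concat([ds.records.assign(replicate=i) for i in range(3)],
                         ignore_index=True)
        ds3 = DepletionDataset(reps, marker=ds.marker, loq=ds.loq, mrl=ds.mrl)
        pooled = fit_depletion_regression(ds3)
        collapsed = fit_depletion_regression(ds3, per_animal_means=True)
        assert pooled.n == 3 * collapsed.n
        assert collapsed.slope == pytest.approx(pooled.slope, rel=1e-12)

    def test_curved_data_flagged_by_lack_of_fit(self):
        rng = np.random.default_rng(3)
        rows = []
        for a in range(8):
            for t in (1.0, 2.0, 4.0, 8.0, 16.0, 24.0):
                c = 100 * np.exp(-0.5 * t) + 20 * np.exp(-0.05 * t)
                rows.append({"animal_id": f"g{a}", "time_h": t,
                             "conc_ng_ml": c * np.exp(rng.normal(0, 0.02))})
        ds = build_depletion_dataset(pd.DataFrame(rows), drop_pre_peak=False)
        fit = fit_depletion_regression(ds)
        assert fit.lack_of_fit_p < 0.05


class TestToleranceLimit:
    def zero_noise_fit(self):
        ds = build_depletion_dataset(make_depletion_frame(n_animals=8))
        return fit_depletion_regression(ds)

    def test_zero_residual_collapses_to_mean_line(self):
        fit = self.zero_noise_fit()
        for x in (0.0, 10.0, 40.0):
            assert tolerance_limit(fit, x, 0.95, 0.95) == pytest.approx(
                fit.mean_line(x), abs=1e-9)
            assert tolerance_limit(fit, x, 0.99, 0.99) == pytest.approx(
                fit.mean_line(x), abs=1e-9)

    def test_large_n_limit_is_normal_quantile(self):
        fit = ToleranceLimitFit(intercept=4.6, slope=-0.1, residual_sd=0.2,
                                n=100_000, t_mean=12.0, sxx=5e5,
                                t_min=2.0, t_max=24.0, slope_p_one_sided=0.0)
        tl = tolerance_limit(fit, 12.0, 0.95, 0.95)
        assert tl == pytest.approx(fit.mean_line(12.0) + 1.6449 * 0.2,
                                   rel=1e-2)

    def test_bound_sits_above_mean_line(self):
        rng = np.random.default_rng(9)
        df = make_depletion_frame(n_animals=8, resid_sd=0.15, rng=rng)
        fit = fit_depletion_regression(build_depletion_dataset(df))
        xs = np.linspace(0, 60, 30)
        assert np.all(tolerance_limit(fit, xs, 0.95, 0.95)
                      >= fit.mean_line(xs))


class TestWithdrawalTime:
    def test_zero_noise_analytic_crossing(self):
        ds = build_depletion_dataset(make_depletion_frame(n_animals=8))
        fit = fit_depletion_regression(ds)
        wdt = withdrawal_time(fit, 0.4, 0.95, 0.95)
        assert wdt == pytest.approx(ANALYTIC_WDT, abs=1e-6)

    def test_limit_above_initial_concentration_gives_zero(self):
        ds = build_depletion_dataset(make_depletion_frame(n_animals=8))
        fit = fit_depletion_regression(ds)
        assert withdrawal_time(fit, 200.0, 0.95, 0.95) == 0.0

    def test_monotone_in_percentile_and_mrl(self):
        rng = np.random.default_rng(21)
        df = make_depletion_frame(n_animals=8, resid_sd=0.15, rng=rng)
        fit = fit_depletion_regression(build_depletion_dataset(df))
        w95 = withdrawal_time(fit, 0.4, 0.95, 0.95)
        w99 = withdrawal_time(fit, 0.4, 0.99, 0.95)
        w_higher_mrl = withdrawal_time(fit, 0.9, 0.95, 0.95)
        assert w99 > w95
        assert w_higher_mrl < w95

    def test_base_invariance_under_log_rescaling(self):
        # running on log10-scale data with a correspondingly rescaled limit
        # must give identical withdrawal times
        rng = np.random.default_rng(17)
        df = make_depletion_frame(n_animals=8, resid_sd=0.1, rng=rng)
        ds = build_depletion_dataset(df, mrl=0.4)
        fit_ln = fit_depletion_regression(ds)
        scaled = DepletionDataset(
            ds.records.assign(ln_conc=ds.records["ln_conc"] / math.log(10)),
            marker=ds.marker, loq=ds.loq,
            mrl=math.exp(math.log10(0.4)))
        fit_10 = fit_depletion_regression(scaled)
        w_ln = withdrawal_time(fit_ln, 0.4, 0.95, 0.95)
        w_10 = withdrawal_time(fit_10, scaled.mrl, 0.95, 0.95)
        assert w_ln == pytest.approx(w_10, abs=1e-9)


class TestOutlierScreen:
    def test_homogeneous_data_has_no_exclusions(self):
        rng = np.random.default_rng(5)
        df = make_depletion_frame(n_animals=8, resid_sd=0.1, rng=rng)
        excluded, _, _ = detect_outlier_animals(build_depletion_dataset(df))
        assert excluded == []

    def test_gross_outlier_animal_flagged_and_refit(self):
        rng = np.random.default_rng(6)
        df = make_depletion_frame(n_animals=8, resid_sd=0.05, rng=rng)
        df.loc[df["animal_id"] == "goat-08", "conc_ng_ml"] *= 20.0
        ds = build_depletion_dataset(df)
        excluded, reduced, refit = detect_outlier_animals(ds)
        assert excluded == ["goat-08"]
        assert reduced.n_animals == 7
        assert refit.residual_sd < fit_depletion_regression(ds).residual_sd

    def test_infinite_threshold_never_excludes(self):
        rng = np.random.default_rng(6)
        df = make_depletion_frame(n_animals=8, resid_sd=0.05, rng=rng)
        df.loc[df["animal_id"] == "goat-08", "conc_ng_ml"] *= 20.0
        excluded, _, _ = detect_outlier_animals(
            build_depletion_dataset(df), threshold=math.inf)
        assert excluded == []


class TestRounding:
    @pytest.mark.parametrize("wdt,expected", [(34.1, 36.0), (37.9, 48.0),
                                              (51.5, 60.0), (36.0, 36.0),
                                              (0.0, 0.0)])
    def test_next_milking_interval(self, wdt, expected):
        assert round_to_milking(wdt, 12.0) == expected

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            round_to_milking(-1.0, 12.0)

    def test_rounding_gap_is_below_one_interval(self):
        rng = np.random.default_rng(13)
        for wdt in rng.uniform(0, 120, 50):
            rounded = round_to_milking(wdt, 12.0)
            assert 0 <= rounded - wdt < 12.0
            assert rounded % 12.0 == 0.0


class TestRegulatoryPipelines:
    def test_ema_zero_noise_returns_analytic_crossing(self):
        ds = build_depletion_dataset(make_depletion_frame(n_animals=8))
        res = ema_sclr(ds)
        assert res.continuous_wdt == pytest.approx(ANALYTIC_WDT, abs=0.01)
        assert res.rounded_wdt == 48.0

    def test_noise_lengthens_the_interval(self):
        rng = np.random.default_rng(14)
        df = make_depletion_frame(n_animals=8, resid_sd=0.15, rng=rng)
        res = ema_sclr(build_depletion_dataset(df))
        assert res.continuous_wdt > ANALYTIC_WDT

    def test_flat_data_not_calculable(self):
        rng = np.random.default_rng(15)
        df = make_depletion_frame(n_animals=6, lam=0.0, c0=50.0,
                                  resid_sd=0.2, rng=rng)
        with pytest.raises(NotCalculableError, match="slope"):
            ema_sclr(build_depletion_dataset(df))

    def test_fda_requires_augmentation_for_eight_animals(self):
        ds = build_depletion_dataset(make_depletion_frame(n_animals=8))
        with pytest.raises(DataFormatError, match="10 animals"):
            fda_milk_discard(ds)

    def test_fda_zero_noise_augmentation_matches_ema(self):
        ds = build_depletion_dataset(make_depletion_frame(n_animals=8))
        res = fda_milk_discard(ds, AugmentationSpec(intra_assay_cv=0.0, seed=1))
        assert res.continuous_wdt == pytest.approx(ANALYTIC_WDT, abs=0.01)
        assert res.diagnostics["n_animals"] == 10

    def test_fda_interval_at_least_ema_on_identical_data(self):
        rng = np.random.default_rng(16)
        df = make_depletion_frame(n_animals=12, resid_sd=0.15, rng=rng)
        ds = build_depletion_dataset(df)
        # replicate each record three times so both methods accept it as-is
        reps = pd.concat(
            [ds.records.assign(replicate=i) for i in range(3)],
            ignore_index=True)
        ds3 = DepletionDataset(reps, marker=ds.marker, loq=ds.loq, mrl=ds.mrl)
        ema = ema_sclr(ds3)
        fda = fda_milk_discard(ds3)
        assert fda.continuous_wdt >= ema.continuous_wdt
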