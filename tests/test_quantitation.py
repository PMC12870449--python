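import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from clcsense import (
    AssaySeries,
    calibrate_assay,
    channel_relative_intensity,
    delta_T,
    detect_linear_range,
    fit_calibration,
    green_relative_intensity,
    haze_percent,
    quantify_image_series,
)
from clcsense.quantitation import default_roi
from clcsense.synthetic import AssayModel, generate_readout_series


def ols_normal_equations(x, y):
    """Independent closed-form simple OLS: slope, intercept, intercept SE, R2."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    m = np.sum((x - xbar) * (y - ybar)) / sxx
    b = ybar - m * xbar
    resid = y - (b + m * x)
    sigma2 = np.sum(resid**2) / (n - 2)
    s_b = np.sqrt(sigma2 * (1.0 / n + xbar**2 / sxx))
    tss = np.sum((y - ybar) ** 2)
    r2 = 1.0 - np.sum(resid**2) / tss
    return m, b, s_b, r2


class TestChannelRelativeIntensity:
    def test_uniform_gray_is_one_third(self):
        img = np.full((20, 20, 3), 128, dtype=np.uint8)
        st_ = channel_relative_intensity(img, channel="R")
        assert st_.relative_intensity_pct == pytest.approx(100.0 / 3.0, abs=1e-9)

    def test_pure_red_is_100(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        img[..., 0] = 255
        assert channel_relative_intensity(
            img, roi=(0, 10, 0, 10), channel="R"
        ).relative_intensity_pct == pytest.approx(100.0)

    def test_half_red_half_green_brute_force(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        img[:, :4, 0] = 200
        img[:, 4:, 1] = 100
        got = channel_relative_intensity(img, roi=(0, 8, 0, 8), channel="R")
        # per-pixel python-loop oracle
        sums = [0, 0, 0]
        for r in range(8):
            for c in range(8):
                for k in range(3):
                    sums[k] += int(img[r, c, k])
        expected = 100.0 * sums[0] / sum(sums)
        assert got.relative_intensity_pct == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(100.0 * 200.0 / 300.0, abs=1e-12)

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_channels_sum_to_100(self, seed):
        img = np.random.default_rng(seed).integers(
            0, 256, size=(12, 12, 3), dtype=np.uint8
        )
        total = sum(
            channel_relative_intensity(img, roi=(0, 12, 0, 12), channel=ch
                                       ).relative_intensity_pct
            for ch in "RGB"
        )
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_green_variant_and_gray(self):
        img = np.full((10, 10, 3), 77, dtype=np.uint8)
        assert green_relative_intensity(img).relative_intensity_pct == pytest.approx(
            100.0 / 3.0
        )
        img2 = np.zeros((10, 10, 3), dtype=np.uint8)
        img2[..., 1] = 10
        assert green_relative_intensity(
            img2, roi=(0, 10, 0, 10)
        ).relative_intensity_pct == pytest.approx(100.0)

    def test_all_black_roi_rejected(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="black"):
            channel_relative_intensity(img, roi=(0, 10, 0, 10))

    def test_roi_outside_extent_rejected(self):
        img = np.full((10, 10, 3), 1, dtype=np.uint8)
        with pytest.raises(ValueError, match="ROI"):
            channel_relative_intensity(img, roi=(0, 11, 0, 10))

    def test_default_roi_trims_border(self):
        assert default_roi((100, 200, 3)) == (5, 95, 10, 190)


class TestHazeAndDeltaT:
    @pytest.mark.parametrize(
        "i_d,i_t,expected", [(0.0, 80.0, 0.0), (50.0, 100.0, 50.0), (13.0, 100.0, 13.0)]
    )
    def test_haze_values(self, i_d, i_t, expected):
        assert haze_percent(i_d, i_t) == pytest.approx(expected, abs=1e-12)

    def test_haze_errors(self):
        with pytest.raises(ValueError):
            haze_percent(1.0, 0.0)
        with pytest.raises(ValueError):
            haze_percent(101.0, 100.0)

    @pytest.mark.parametrize(
        "t0,tc,expected",
        [
            (55.0, 55.0, 0.0),
            (60.0, 7.0, 100.0 * 53.0 / 60.0),   # ~88.33
            (70.0, 30.0, 100.0 * 40.0 / 70.0),  # ~57.14
        ],
    )
    def test_delta_T_values(self, t0, tc, expected):
        assert delta_T(t0, tc) == pytest.approx(expected, abs=1e-12)

    def test_delta_T_antitone_in_Tc(self):
        tcs = np.linspace(0.0, 80.0, 30)
        vals = [delta_T(80.0, tc) for tc in tcs]
        assert np.all(np.diff(vals) < 0)

    def test_delta_T_errors(self):
        with pytest.raises(ValueError):
            delta_T(0.0, 10.0)
        with pytest.raises(ValueError):
            delta_T(50.0, -1.0)


def make_series(conc, means, reps=1, noise=None, seed=0):
    rng = np.random.default_rng(seed)
    c = np.repeat(conc, reps)
    y = np.repeat(means, reps)
    if noise:
        y = y + rng.normal(0, noise, size=y.shape)
    r = np.tile(np.arange(1, reps + 1), len(conc))
    return AssaySeries(c, y, r)


class TestFitCalibration:
    def test_exact_line(self):
        conc = np.logspace(-10, -6, 5)
        x = np.log10(conc)
        series = make_series(conc, 2.0 * x + 1.0)
        fit = fit_calibration(series, "log10_concentration")
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)
        assert fit.intercept_sd == pytest.approx(0.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.lod == pytest.approx(0.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(25):
            n = rng.integers(4, 10)
            conc = np.sort(rng.uniform(1e-9, 1e-5, n))
            y = rng.normal(20.0, 5.0, n)
            series = make_series(conc, y)
            fit = fit_calibration(series, "linear_concentration")
            m, b, s_b, r2 = ols_normal_equations(conc, y)
            assert fit.slope == pytest.approx(m, rel=1e-8, abs=1e-12)
            assert fit.intercept == pytest.approx(b, rel=1e-8, abs=1e-12)
            assert fit.intercept_sd == pytest.approx(s_b, rel=1e-8)
            assert fit.r_squared == pytest.approx(r2, rel=1e-8)

    def test_intercept_sd_matches_bootstrap(self):
        rng = np.random.default_rng(77)
        n = 8
        # oracle must regress on the same axis as the fit (log10 c)
        x = np.linspace(-12.0, -5.0, n)
        y = 3.0 + 2.0 * (x - x[0]) + rng.normal(0, 1.0, n)
        series = make_series(10.0**x, y)
        fit = fit_calibration(series, "log10_concentration")
        # residual bootstrap with the small-sample inflation sqrt(n/(n-2))
        m, b, *_ = ols_normal_equations(x, y)
        fitted = b + m * x
        resid = (y - fitted) * np.sqrt(n / (n - 2.0))
        boot = np.empty(2000)
        for i in range(2000):
            yb = fitted + rng.choice(resid, size=n, replace=True)
            _, bb, *_ = ols_normal_equations(x, yb)
            boot[i] = bb
        assert fit.intercept_sd == pytest.approx(boot.std(ddof=1), rel=0.10)

    def test_loq_lod_ratio_forced(self, rng):
        conc = np.logspace(-12, -6, 7)
        y = 5.0 + 2.5 * np.log10(conc / conc[0]) + rng.normal(0, 0.8, 7)
        fit = fit_calibration(make_series(conc, y))
        assert fit.loq / fit.lod == pytest.approx(10.0 / 3.0, rel=1e-12)

    def test_too_few_points_error(self):
        series = make_series(np.array([1e-9, 1e-8]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            fit_calibration(series)

    def test_slope_recovery_from_generator(self):
        model = AssayModel.for_readout("BSA", "haze")
        series, truth = generate_readout_series(model, "haze", seed=1)
        fit = fit_calibration(series)
        assert fit.slope == pytest.approx(truth["slope_per_decade"], rel=0.05)


class TestDetectLinearRange:
    def test_strictly_linear_returns_full_range(self):
        conc = np.logspace(-12, -5, 8)
        series = make_series(conc, np.linspace(10, 45, 8))
        rng_, onset = detect_linear_range(series)
        assert onset is None
        assert rng_ == (conc[0], conc[-1])

    def test_injected_plateau_found(self):
        model = AssayModel.for_readout("BSA", "R_rel", noise_sd=0.0)
        series, truth = generate_readout_series(model, "R_rel", seed=0)
        rng_, onset = detect_linear_range(series)
        j = truth["first_plateau_index"]
        assert onset == j
        assert rng_[1] == pytest.approx(model.concentrations[j - 1])

    def test_constant_series_empty_range_with_warning(self):
        conc = np.logspace(-10, -6, 5)
        series = make_series(conc, np.full(5, 30.0))
        with pytest.warns(UserWarning, match="linear range"):
            rng_, onset = detect_linear_range(series)
        assert rng_ is None

    def test_decreasing_readout_supported(self):
        # transmittance-style series falling with concentration
        model = AssayModel.for_readout("BSA", "T_p", noise_sd=0.0)
        series, _ = generate_readout_series(model, "T_p", seed=0)
        rng_, onset = detect_linear_range(series)
        assert onset is None  # no plateau in the default T_p model

    def test_too_few_concentrations(self):
        series = make_series(np.logspace(-9, -7, 3), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            detect_linear_range(series)


class TestQuantifyImageSeries:
    def test_single_gray_image(self):
        img = np.full((16, 16, 3), 90, dtype=np.uint8)
        series = quantify_image_series([img], [1e-9])
        assert series.readouts[0] == pytest.approx(100.0 / 3.0)
        assert len(series.readouts) == 1

    def test_permutation_invariance(self, rng):
        imgs = [
            rng.integers(1, 256, size=(16, 16, 3)).astype(np.uint8) for _ in range(6)
        ]
        conc = np.repeat(np.logspace(-9, -7, 3), 2)
        fwd = quantify_image_series(imgs, conc)
        perm = [4, 2, 0, 5, 3, 1]
        rev = quantify_image_series(
            [imgs[i] for i in perm], conc[perm]
        )
        assert fwd.grouped().equals(rev.grouped())

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            quantify_image_series([np.zeros((4, 4, 3))], [1e-9, 1e-8])


class TestCalibrateAssayWorkflow:
    def test_reports_excluded_plateau_points(self):
        model = AssayModel.for_readout("BSA", "R_rel", noise_sd=0.0)
        series, truth = generate_readout_series(model, "R_rel", seed=0)
        res = calibrate_assay(series)
        j = truth["first_plateau_index"]
        assert res["plateau_start_index"] == j
        assert res["excluded_concentrations"] == list(model.concentrations[j:])
        assert res["semilog_fit"].r_squared > 0.999
        assert res["low_range_fit"].transform == "linear_concentration"
        assert res["loq"] / res["lod"] == pytest.approx(10.0 / 3.0)
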