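"""Box-Cox transform recovery, spline mean curves, SD models, bands."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from steroidpanel import (
    CycleModelConfig,
    CyclicMean,
    build_reference_band,
    estimate_lambda,
    fit_mean_curve,
    fit_sd_model,
    flag_against_band,
    generate_cycle_series,
)
from steroidpanel.reference_intervals import boxcox_inverse, boxcox_transform


class TestLambda:
    def test_lognormal_sample_recovers_log_transform(self, rng):
        x = rng.lognormal(3.0, 0.6, 5000)
        assert -0.15 <= estimate_lambda(x) <= 0.15

    def test_normal_sample_recovers_identity(self, rng):
        x = rng.normal(100.0, 10.0, 5000)
        assert 0.7 <= estimate_lambda(x) <= 1.3

    def test_constant_sample_warns_identity(self):
        with pytest.warns(UserWarning, match="constant"):
            assert estimate_lambda(np.full(20, 5.0)) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            estimate_lambda(np.array([1.0] * 9 + [-1.0]))

    @given(st.floats(-2.0, 2.0).map(lambda v: round(v, 1)),
           st.floats(0.05, 500.0))
    def test_boxcox_round_trip(self, lam, x):
        assert boxcox_inverse(boxcox_transform(x, lam), lam) == pytest.approx(
            x, rel=1e-10, abs=1e-10)


class TestMeanCurve:
    def test_constant_data(self):
        day = np.repeat(np.arange(1, 11), 3)
        curve = fit_mean_curve(day, np.full(day.size, 4.2))
        assert np.allclose(curve.fitted, 4.2, atol=1e-8)

    def test_linear_trend_reproduced_exactly(self):
        day = np.repeat(np.arange(1, 15), 2)
        y = 2.0 + 0.5 * day
        curve = fit_mean_curve(day, y)
        assert np.allclose(curve.fitted, 2.0 + 0.5 * curve.grid_days, atol=1e-6)

    def test_too_few_days_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_mean_curve(np.repeat([1, 2], 10), np.arange(20.0))

    def test_recovery_on_simulated_cycles(self):
        # smooth testosterone trajectory, CV 15%, 32 subjects
        cfg = CycleModelConfig(
            n_subjects=32,
            analyte_means={"testosterone": CyclicMean(22.0, mid_amp=8.0,
                                                      mid_width=4.0)},
            cycle_length_range=(28, 28),  # shared length -> exact truth curve
            residual_cv=0.15, seed=21)
        series = generate_cycle_series(cfg)
        sigma = np.sqrt(np.log1p(0.15**2))
        day = series["cycle_day"].to_numpy(float)
        logged = np.log(series["testosterone"].to_numpy(float))
        curve = fit_mean_curve(day, logged)
        truth = np.log(cfg.analyte_means["testosterone"](curve.grid_days,
                                                         28.0)) - sigma**2 / 2
        max_err = np.max(np.abs(curve.fitted - truth))
        assert max_err < 0.5 * sigma


class TestSDModel:
    def test_all_zero_residuals(self):
        model = fit_sd_model(np.repeat(np.arange(1, 11), 3), np.zeros(30))
        assert model.kind == "constant" and model.sd == 0.0

    def test_homoscedastic_prefers_constant(self, rng):
        # 32 subjects per day, the daily-sampling design
        picks = 0
        for _ in range(500):
            day = np.repeat(np.arange(1, 29), 32)
            resid = rng.normal(0, 1.0, day.size)
            picks += fit_sd_model(day, resid).kind == "constant"
        assert picks >= 450  # alpha=0.05 selection rule

    def test_heteroscedastic_prefers_polynomial(self, rng):
        picks = 0
        for _ in range(500):
            day = np.repeat(np.arange(1, 29), 32)
            sd = 1.0 + day / 28.0  # SD doubles across the cycle
            resid = rng.normal(0, sd)
            picks += fit_sd_model(day, resid).kind == "polynomial"
        assert picks >= 450

    def test_forced_models(self, rng):
        day = np.repeat(np.arange(1, 11), 4)
        resid = rng.normal(0, 1 + day / 10.0)
        assert fit_sd_model(day, resid, model="constant").kind == "constant"
        assert fit_sd_model(day, resid, model="poly").kind == "polynomial"

    def test_polynomial_prediction_floored_positive(self, rng):
        day = np.repeat(np.arange(1, 29), 2)
        resid = rng.normal(0, 0.1 + 2.0 * (day > 20), day.size)
        model = fit_sd_model(day, resid, model="poly")
        assert (model.predict(np.arange(1.0, 29.0)) > 0).all()


class TestReferenceBand:
    def test_constant_hormone_collapses(self):
        cycle = pd.DataFrame({
            "subject_id": np.repeat([f"N{i}" for i in range(4)], 28),
            "cycle_day": np.tile(np.arange(1, 29), 4),
            "lh": 9.0,
        })
        with pytest.warns(UserWarning, match="constant"):
            band = build_reference_band(cycle, "lh")
        assert np.allclose(band.mean_curve, 9.0, atol=1e-8)
        assert np.allclose(band.lower_curve, band.upper_curve, atol=1e-6)

    def test_log_path_closed_form(self):
        # lambda = 0: limits are exp(m -/+ 2s)
        m, s = 2.0, 0.3
        assert boxcox_inverse(m - 2 * s, 0.0) == pytest.approx(np.exp(m - 2 * s))
        assert boxcox_inverse(m + 2 * s, 0.0) == pytest.approx(np.exp(m + 2 * s))

    def test_band_ordering_everywhere(self, cycle_series):
        for analyte in ("lh", "testosterone", "androstenedione",
                        "17oh_progesterone"):
            band = build_reference_band(cycle_series, analyte)
            assert (band.lower_curve <= band.mean_curve + 1e-9).all()
            assert (band.mean_curve <= band.upper_curve + 1e-9).all()
            assert np.isfinite(band.mean_curve).all()
            assert (band.upper_curve > 0).all()

    def test_flagging_rules(self, cycle_series):
        band = build_reference_band(cycle_series, "testosterone")
        samples = pd.DataFrame({
            "cycle_day": [5.0, 5.0, 5.0],
            "testosterone": [band.curves_at(5)[1][()],  # on the mean curve
                             band.curves_at(5)[2][()] * 1.5,
                             band.curves_at(5)[0][()] * 0.5],
        })
        assert list(flag_against_band(band, samples)) == ["within", "above", "below"]

    def test_shifted_cases_flagged_above(self, cycle_series, rng):
        # cases shifted +2 SD on the transformed scale put their median on
        # the upper limit: about half flag above, versus ~2.5% unshifted
        band = build_reference_band(cycle_series, "testosterone")
        days = rng.integers(band.grid_days.min(), band.grid_days.max() + 1, 4000)
        sd = band.sd_model.predict(days.astype(float))
        mean_t = band.mean_model.predict(days.astype(float))
        noise = rng.normal(0, sd)
        shifted = boxcox_inverse(mean_t + 2 * sd + noise, band.lam)
        unshifted = boxcox_inverse(mean_t + noise, band.lam)
        frame = pd.DataFrame({"cycle_day": days, "testosterone": shifted})
        frac_shifted = (flag_against_band(band, frame) == "above").mean()
        frame["testosterone"] = unshifted
        frac_null = (flag_against_band(band, frame) == "above").mean()
        assert frac_shifted == pytest.approx(0.5, abs=0.03)
        assert frac_null < 0.05
        assert frac_shifted > 10 * frac_null

    def test_nearest_day_rule_outside_grid(self, cycle_series):
        band = build_reference_band(cycle_series, "lh")
        lo, hi = band.grid_days.min(), band.grid_days.max()
        inside = band.curves_at([lo, hi])
        outside = band.curves_at([lo - 3, hi + 3])
        assert np.allclose(inside, outside)
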