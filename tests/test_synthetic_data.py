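"""Generator calibration, determinism and constraint tests."""

import numpy as np
import pandas as pd
import pytest

from steroidpanel import (
    AnalyteSpec,
    AssayBiasConfig,
    CohortConfig,
    CycleModelConfig,
    CyclicMean,
    QCPoolSpec,
    calibrate_assay_bias,
    default_cohort_config,
    default_cycle_config,
    expected_percent_difference,
    generate_calibration,
    generate_cohort,
    generate_cycle_series,
    generate_qc_replicates,
    percent_difference,
    simulate_paired_assays,
)
from steroidpanel.analytes import DEFAULT_LOQ


def _single_analyte_config(spec, n, seed):
    return CohortConfig(n_pcos=n, n_control=1, pcos_specs=(spec,),
                        control_specs=(spec,), correlation=0.0, seed=seed)


class TestCohort:
    def test_median_calibration_large_n(self):
        # generator's own calibration: sample median ~= configured target
        spec = AnalyteSpec("testosterone", 49.2, 125.3, loq=25.0)
        cohort = generate_cohort(_single_analyte_config(spec, 5000, seed=3))
        med = np.median(cohort.loc[cohort.group == "pcos", "testosterone"])
        assert abs(med - 49.2) / 49.2 < 0.03

    def test_p97_5_calibration_large_n(self):
        spec = AnalyteSpec("androstenedione", 202.9, 476.2)
        cohort = generate_cohort(_single_analyte_config(spec, 20000, seed=4))
        q = np.percentile(cohort.loc[cohort.group == "pcos", "androstenedione"], 97.5)
        assert abs(q - 476.2) / 476.2 < 0.05

    def test_seed_determinism(self):
        a = generate_cohort(default_cohort_config(seed=5))
        b = generate_cohort(default_cohort_config(seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_group_sizes_and_columns(self, small_cohort):
        assert (small_cohort.group == "pcos").sum() == 52
        assert (small_cohort.group == "control").sum() == 42
        for col in ("subject_id", "age", "bmi", "testosterone", "lh"):
            assert col in small_cohort.columns

    def test_inconsistent_percentiles_rejected(self):
        with pytest.raises(ValueError, match="below"):
            AnalyteSpec("testosterone", median_target=100.0, p97_5_target=50.0)

    def test_censoring_realism_pregnenolone(self):
        # the published floor implies the majority of values sit below LOQ
        cohort = generate_cohort(default_cohort_config(n_control=4000, seed=6))
        controls = cohort[cohort.group == "control"]
        frac = (controls["pregnenolone"] < DEFAULT_LOQ["pregnenolone"]).mean()
        assert frac > 0.5

    def test_correlation_induces_rank_association(self):
        cfg = default_cohort_config(n_pcos=3000, correlation=0.6, seed=8)
        cohort = generate_cohort(cfg)
        pcos = cohort[cohort.group == "pcos"]
        # androstenedione -> testosterone are pathway-adjacent
        rho = pcos[["androstenedione", "testosterone"]].corr("spearman").iloc[0, 1]
        assert rho > 0.4


class TestCycleSeries:
    def test_noiseless_constant_mean(self):
        cfg = CycleModelConfig(
            n_subjects=5, analyte_means={"lh": CyclicMean(baseline=7.0)},
            residual_cv=0.0, max_missing_days=0, seed=1)
        series = generate_cycle_series(cfg)
        assert np.allclose(series["lh"], 7.0)

    def test_missing_day_and_length_constraints(self):
        series = generate_cycle_series(default_cycle_config(seed=2))
        for _, block in series.groupby("subject_id"):
            length = block["cycle_length"].iloc[0]
            assert 25 <= length <= 35
            assert length - len(block) <= 4
            assert block["cycle_day"].between(1, length).all()

    def test_lh_peak_in_configured_window(self):
        cfg = default_cycle_config(seed=3, residual_cv=0.0)
        series = generate_cycle_series(cfg)
        mid_frac = cfg.analyte_means["lh"].mid_frac
        for _, block in series.groupby("subject_id"):
            length = block["cycle_length"].iloc[0]
            peak_day = block.loc[block["lh"].idxmax(), "cycle_day"]
            assert abs(peak_day - mid_frac * length) <= 1.0

    def test_cycle_length_range_validated(self):
        with pytest.raises(ValueError, match="25, 35"):
            CycleModelConfig(n_subjects=3, analyte_means={"lh": CyclicMean(1.0)},
                             cycle_length_range=(20, 35))

    def test_seed_determinism(self):
        a = generate_cycle_series(default_cycle_config(seed=9))
        b = generate_cycle_series(default_cycle_config(seed=9))
        pd.testing.assert_frame_equal(a, b)


class TestPairedAssays:
    def test_identity_assay(self, small_cohort):
        pairs = simulate_paired_assays(small_cohort,
                                       AssayBiasConfig(bias=1.0, scatter=0.0))
        assert np.allclose(
            percent_difference(pairs["ria_value"], pairs["lcms_value"]), 0.0)

    def test_pure_bias_three_gives_100_percent(self, small_cohort):
        pairs = simulate_paired_assays(small_cohort,
                                       AssayBiasConfig(bias=3.0, scatter=0.0))
        pct = percent_difference(pairs["ria_value"], pairs["lcms_value"])
        assert np.allclose(pct, 100.0)  # 100 x (3x - x)/(2x)

    def test_calibrated_bias_recovers_target_moments(self):
        cfg = calibrate_assay_bias(31.0, 38.0, seed=12)
        mean, sd = expected_percent_difference(cfg.bias, cfg.scatter)
        assert mean == pytest.approx(31.0, abs=1e-6)
        assert sd == pytest.approx(38.0, abs=1e-6)
        ref = pd.DataFrame({"testosterone": np.full(10000, 30.0)})
        pairs = simulate_paired_assays(ref, cfg, analytes=["testosterone"])
        pct = percent_difference(pairs["ria_value"], pairs["lcms_value"])
        assert np.mean(pct) == pytest.approx(31.0, abs=2.0)

    def test_empty_profiles_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_paired_assays(pd.DataFrame(), AssayBiasConfig())

    def test_invalid_bias_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            AssayBiasConfig(bias=-1.0)


class TestQCReplicates:
    def test_zero_cv_degenerate(self):
        reps = generate_qc_replicates({"low": QCPoolSpec(50.0, 0.0, 0.0)},
                                      n_runs=3, n_reps=4, seed=0)
        assert np.allclose(reps["value"], 50.0)

    def test_layout_shape(self):
        reps = generate_qc_replicates(
            {k: QCPoolSpec(m, 5.0, 5.0) for k, m in
             [("low", 50.0), ("mid", 500.0), ("high", 5000.0)]},
            n_runs=5, n_reps=10, seed=0)
        assert len(reps) == 150
        assert set(reps["level"]) == {"low", "mid", "high"}

    def test_cv_converges_to_target(self):
        from steroidpanel import intra_run_cv
        reps = generate_qc_replicates({"low": QCPoolSpec(100.0, 13.1, 0.0)},
                                      n_runs=1, n_reps=10000, seed=1)
        assert intra_run_cv(reps["value"]) == pytest.approx(13.1, abs=0.5)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            QCPoolSpec(100.0, -1.0)


class TestCalibrationSeries:
    def test_noiseless_identity(self):
        series = generate_calibration(cv=0.0, seed=0)
        assert np.allclose(series.points["measured"], series.points["nominal"])

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match=">=5"):
            generate_calibration(levels=[25, 100, 1000], cv=0.1)

    def test_determinism(self):
        a = generate_calibration(cv=0.1, seed=42).points
        b = generate_calibration(cv=0.1, seed=42).points
        pd.testing.assert_frame_equal(a, b)
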