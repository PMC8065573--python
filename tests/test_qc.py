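"""Calibration fitting/averaging, slope stability, LOQ rule, tune checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccldkit.library import CalibrationLine
from ccldkit.qc import (CalibrationBatch, QCError, TuneRecord, average_curves,
                        check_tune, determine_loq, fit_calibration,
                        pooled_refit, slope_rsd, tune_stability)
from ccldkit.simulate import simulate_calibration_series, simulate_tune_log

GLUCOSE_LEVELS = [0, 5, 50, 100, 200, 500, 1000, 1500]


def batches_from_slopes(slopes_by_day):
    out = []
    for day, slopes in slopes_by_day.items():
        for i, s in enumerate(slopes):
            out.append(CalibrationBatch(
                batch_id=f"{day}_r{i}", day=day,
                rpas={0.0: [0.0], 100.0: [100.0 * s]},
            ))
    return out


class TestFitCalibration:
    def test_exact_points_recover_glucose_line(self):
        slope, intercept = 0.00777, -0.04160
        pts = [(c, slope * c + intercept) for c in GLUCOSE_LEVELS]
        line = fit_calibration(pts)
        assert line.slope == pytest.approx(slope, abs=1e-12)
        assert line.intercept == pytest.approx(intercept, abs=1e-12)
        assert line.r_squared == pytest.approx(1.0, abs=1e-12)
        assert line.levels == [float(c) for c in GLUCOSE_LEVELS]

    def test_two_points_always_perfect_fit(self):
        line = fit_calibration([(5.0, 1.0), (50.0, 17.0)])
        assert line.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_identical_concentrations_rejected(self):
        with pytest.raises(QCError):
            fit_calibration([(5.0, 1.0), (5.0, 1.1)])

    def test_jittered_slope_within_analytic_se(self):
        rng = np.random.default_rng(123)
        slope, intercept, sd = 0.01, -0.05, 0.02
        x = np.array([0.0, 5.0, 50.0, 100.0, 200.0])
        reps = []
        for _ in range(200):
            y = slope * x + intercept + rng.normal(0, sd, x.size)
            reps.append(fit_calibration(list(zip(x, y))).slope)
        # sd of the OLS slope: sigma / sqrt(Sxx)
        sxx = float(np.sum((x - x.mean()) ** 2))
        se = sd / np.sqrt(sxx)
        assert np.std(reps) == pytest.approx(se, rel=0.2)
        assert np.mean(reps) == pytest.approx(slope, abs=3 * se / np.sqrt(200))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(3, 12),
    )
    def test_matches_normal_equations_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(0, 200, n))
        x[1] = x[0] + 1.0  # ensure distinct
        y = rng.normal(0, 1, n)
        line = fit_calibration(list(zip(x, y)))
        A = np.column_stack([x, np.ones(n)])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert line.slope == pytest.approx(beta[0], rel=1e-10, abs=1e-10)
        assert line.intercept == pytest.approx(beta[1], rel=1e-10, abs=1e-10)

    def test_r2_one_iff_zero_residuals(self):
        pts = [(0.0, -0.05), (50.0, 0.45), (100.0, 0.95)]
        line = fit_calibration(pts)
        resid = [r - line.predict(c) for c, r in pts]
        assert line.r_squared == pytest.approx(1.0, abs=1e-12)
        assert max(abs(r) for r in resid) < 1e-12
        line2 = fit_calibration(pts[:-1] + [(100.0, 1.5)])
        assert line2.r_squared < 1.0


class TestAveraging:
    def test_identical_curves_average_to_themselves(self):
        c = CalibrationLine(slope=0.01, intercept=-0.05, r_squared=0.99)
        avg = average_curves([c] * 9)
        assert avg.line.slope == c.slope
        assert avg.line.intercept == c.intercept
        assert len(avg.batch_lines) == 9

    def test_mean_of_two_slopes(self):
        a = CalibrationLine(slope=0.010, intercept=-0.04, r_squared=0.99)
        b = CalibrationLine(slope=0.020, intercept=-0.06, r_squared=0.97)
        avg = average_curves([a, b])
        assert avg.line.slope == pytest.approx(0.015)
        assert avg.line.intercept == pytest.approx(-0.05)
        assert avg.line.r_squared == pytest.approx(0.98)

    def test_mismatched_levels_rejected(self):
        a = CalibrationLine(slope=0.01, intercept=0.0, r_squared=1.0, levels=[0, 5])
        b = CalibrationLine(slope=0.01, intercept=0.0, r_squared=1.0, levels=[0, 50])
        with pytest.raises(QCError, match="mismatched"):
            average_curves([a, b])

    def test_nine_noisy_alanine_refits_average_near_truth(self, library):
        entry = library.get("M004")
        batches = simulate_calibration_series(entry, cv=0.05, seed=77)
        assert len(batches) == 9
        curves = [fit_calibration(b.points()) for b in batches]
        avg = average_curves(curves)
        assert avg.line.slope == pytest.approx(0.0181, rel=0.02)

    def test_pooled_refit_on_exact_data_matches_mean(self, library):
        entry = library.get("M004")
        batches = simulate_calibration_series(entry, cv=0.0, seed=0)
        pooled = pooled_refit(batches)
        assert pooled.slope == pytest.approx(entry.calibration.slope, abs=1e-12)


class TestSlopeRSD:
    def test_identical_slopes_zero_rsd(self):
        batches = batches_from_slopes({"d1": [0.01, 0.01], "d2": [0.01, 0.01]})
        intra, inter = slope_rsd(batches)
        assert intra == pytest.approx(0.0, abs=1e-12)
        assert inter == pytest.approx(0.0, abs=1e-12)

    def test_inter_day_rsd_of_9_10_11(self):
        batches = batches_from_slopes({"d1": [9.0], "d2": [10.0], "d3": [11.0]})
        _, inter = slope_rsd(batches)
        assert inter == pytest.approx(10.0)

    def test_single_batch_undefined(self):
        batches = batches_from_slopes({"d1": [0.01]})
        intra, inter = slope_rsd(batches)
        assert np.isnan(intra) and np.isnan(inter)

    def test_simulated_day_effect_shows_in_inter_day_rsd(self, library):
        entry = library.get("M018")
        batches = simulate_calibration_series(
            entry, replicates=3, days=12, cv=0.0, day_effect_cv=0.05, seed=5
        )
        intra, inter = slope_rsd(batches)
        assert intra == pytest.approx(0.0, abs=1e-9)  # no within-day noise
        assert inter == pytest.approx(5.0, rel=0.5)   # Monte-Carlo slack


class TestLOQ:
    def test_low_5uM_snr_pushes_loq_to_50(self):
        assert determine_loq([(5, 6), (50, 30)]) == 50.0

    def test_snr_above_threshold_at_5(self):
        assert determine_loq([(5, 12), (50, 80)]) == 5.0

    def test_all_below_threshold_unset(self):
        assert determine_loq([(5, 2), (50, 8)]) is None

    def test_empty_series_rejected(self):
        with pytest.raises(QCError):
            determine_loq([])

    def test_monotone_in_noise(self):
        series = [(5.0, 11.0), (50.0, 60.0), (100.0, 120.0)]
        loq0 = determine_loq(series)
        for k in (0.9, 0.5, 0.1):
            degraded = [(c, s * k) for c, s in series]
            loq1 = determine_loq(degraded)
            assert loq1 is None or loq1 >= loq0


class TestTune:
    def test_dftpp_ratios_pass(self):
        rec = TuneRecord(timestamp="d1",
                         abundance={69: 200000.0, 219: 110000.0, 502: 4000.0})
        chk = check_tune(rec)
        assert chk.relative_abundance == {69: 100.0, 219: 55.0, 502: 2.0}
        assert chk.passed

    def test_inflated_219_fails(self):
        rec = TuneRecord(timestamp="d1",
                         abundance={69: 200000.0, 219: 200000.0, 502: 4000.0})
        chk = check_tune(rec)
        assert chk.relative_abundance[219] == pytest.approx(100.0)
        assert not chk.passed

    def test_missing_ion_rejected(self):
        rec = TuneRecord(timestamp="d1", abundance={69: 200000.0})
        with pytest.raises(QCError, match="missing ion"):
            check_tune(rec)

    def test_scale_invariance(self):
        a = {69: 200000.0, 219: 130000.0, 502: 4400.0}
        rec1 = TuneRecord(timestamp="d1", abundance=a)
        rec2 = TuneRecord(timestamp="d1", abundance={m: 7.3 * v for m, v in a.items()})
        c1, c2 = check_tune(rec1), check_tune(rec2)
        assert c1.relative_abundance == pytest.approx(c2.relative_abundance)
        assert c1.passed == c2.passed


class TestTuneStability:
    def test_constant_log_zero_rsd(self):
        recs = simulate_tune_log(days=10, seed=0)
        out = tune_stability(recs)
        for mz in (69, 219, 502):
            assert out["absolute_rsd"][mz] == pytest.approx(0.0, abs=1e-10)
            assert out["relative_rsd"][mz] == pytest.approx(0.0, abs=1e-10)

    def test_common_mode_drift_cancels_in_relative(self):
        recs = simulate_tune_log(days=30, common_cv=0.2, seed=1)
        out = tune_stability(recs)
        assert out["absolute_rsd"][219] > 5.0
        assert out["relative_rsd"][219] == pytest.approx(0.0, abs=1e-9)

    def test_independent_noise_propagates_as_sqrt2(self):
        # ratio of two ions with independent 5% CV noise has CV ≈ √2·5%
        recs = simulate_tune_log(days=4000, per_ion_cv=0.05, seed=2)
        out = tune_stability(recs)
        expected = np.sqrt(2) * 5.0
        assert out["relative_rsd"][219] == pytest.approx(expected, rel=0.1)
        assert out["absolute_rsd"][219] == pytest.approx(5.0, rel=0.1)

    def test_requires_two_records(self):
        with pytest.raises(QCError):
            tune_stability(simulate_tune_log(days=1, seed=0))
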