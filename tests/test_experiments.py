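"""Dispersion metric, angle scan, calibration, error statistics."""

import numpy as np
import pandas as pd
import pytest
import warnings

import sfrmodel as s
from sfrmodel.experiments import (calibrate_constants, error_statistics,
                                  relative_dispersion, scan_integration_angles,
                                  stratify_by_psb)


class TestRelativeDispersion:
    def test_identical_in_band_is_zero(self):
        r0 = np.array([1.0, 1.0, 10.0, 0.1])
        p = np.array([5.0, 5.0, 50.0, 0.5])
        assert relative_dispersion(r0, p, target_r0=1.0) == 0.0

    def test_full_spread_is_one(self):
        r0 = np.array([1.0, 1.0])
        p = np.array([1.0, 100.0])
        assert relative_dispersion(r0, p, target_r0=1.0) == 1.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        r0 = rng.uniform(0.5, 2.0, 40)
        p = rng.lognormal(0, 1, 40)
        d1 = relative_dispersion(r0, p, 1.0)
        d2 = relative_dispersion(r0, 137.0 * p, 1.0)
        assert np.isclose(d1, d2, rtol=1e-12)
        assert 0.0 <= d1 <= 1.0

    def test_empty_band_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            relative_dispersion([1.0, 2.0], [1.0, 2.0], target_r0=100.0)


class TestAngleScan:
    def test_full_grid_finds_reference_angles(self, grid, probe22):
        """Noiseless scan over the complete ensemble lands at (1, ~23) deg."""
        psb = np.array([s.psb(m) for m in grid.models])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r0 = np.array([s.predict_R0(p, 0.1, probe22).R0 for p in psb])
        scan = scan_integration_angles(list(grid.models), r0)
        assert scan.optimum.theta_b == 1.0
        assert 20.0 <= scan.optimum.theta_f <= 26.0

    def test_forward_angle_minimum_is_sharp(self, grid, probe22):
        """Along theta_f (at the optimal theta_b) the dispersion has a
        pronounced minimum near 23 deg, degrading clearly on both sides."""
        psb = np.array([s.psb(m) for m in grid.models])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r0 = np.array([s.predict_R0(p, 0.1, probe22).R0 for p in psb])
        scan = scan_integration_angles(list(grid.models), r0)
        slice_f = scan.dispersion_vs_theta_f().set_index("theta_f")
        best = scan.mean_dispersion_at_optimum
        assert slice_f.loc[5.0, "mean_dispersion"] > 3.0 * best
        assert slice_f.loc[60.0, "mean_dispersion"] > 3.0 * best

    def test_surface_exported(self, grid, probe22):
        models = [grid.models[i] for i in stratify_by_psb(grid, 30)]
        rng = np.random.default_rng(1)
        r0 = np.sort(rng.lognormal(-7, 1, 30))
        scan = scan_integration_angles(models, r0, theta_b_max=10,
                                       theta_f_max=30)
        assert {"theta_b", "theta_f", "mean_dispersion"} == \
            set(scan.surface.columns)
        assert len(scan.surface) == 10 * 30
        assert (scan.surface.mean_dispersion >= 0).all()


def _synthetic_calibration_data(probe22, a1, a2, a3, noise, seed):
    rng = np.random.default_rng(seed)
    psb = np.logspace(-6, -3.5, 12)
    rows = []
    for p in psb:
        for musp_d in (0.1, 0.5, 1.0, 5.0, 9.0):
            x = a2 * (p / musp_d ** 2) ** a3
            r0 = (1 + x) * a1 * np.sin(probe22.theta_acc) ** 2 \
                * s.diffuse_reflectance(musp_d)
            r0 *= 1.0 + noise * rng.standard_normal()
            rows.append(dict(na=0.22, psb=p, musp_d=musp_d, r0=r0))
    return pd.DataFrame(rows)


class TestCalibration:
    def test_exact_recovery_noiseless(self, probe22):
        truth = (1.08, 2800.0, 0.74)
        data = _synthetic_calibration_data(probe22, *truth, noise=0.0, seed=0)
        cal = calibrate_constants(data, {0.22: probe22})
        assert np.isclose(cal.stage1.loc[0.22, "a1"], truth[0], rtol=5e-4)
        assert np.isclose(cal.stage1.loc[0.22, "a2"], truth[1], rtol=5e-3)
        assert np.isclose(cal.stage1.loc[0.22, "a3"], truth[2], rtol=5e-4)

    def test_noisy_recovery_within_ci(self, probe22):
        """2% noise: recovery within 3 CI half-widths."""
        truth = (1.08, 2800.0, 0.74)
        data = _synthetic_calibration_data(probe22, *truth, noise=0.02, seed=3)
        cal = calibrate_constants(data, {0.22: probe22})
        row = cal.stage1.loc[0.22]
        assert abs(row.a1 - truth[0]) < 3 * row.a1_ci
        assert abs(row.a2 - truth[1]) < 3 * row.a2_ci
        assert abs(row.a3 - truth[2]) < 3 * row.a3_ci

    def test_stage2_fixes_shared_a1(self, probe22):
        truth = (1.11, 3000.0, 0.75)
        data = _synthetic_calibration_data(probe22, *truth, noise=0.0, seed=1)
        cal = calibrate_constants(data, {0.22: probe22}, a1_shared=1.11)
        assert cal.a1_shared == 1.11
        assert np.isclose(cal.stage2.loc[0.22, "a2"], truth[1], rtol=1e-4)
        assert "a1" not in cal.stage2.columns

    def test_validity_filter_applied(self, probe22):
        data = _synthetic_calibration_data(probe22, 1.1, 3000.0, 0.75,
                                           noise=0.0, seed=2)
        low = data.copy()
        low.loc[low.index[:3], "musp_d"] = 0.01  # should be dropped
        cal_all = calibrate_constants(data, {0.22: probe22})
        cal_low = calibrate_constants(low, {0.22: probe22})
        assert np.isfinite(cal_low.stage1.loc[0.22, "a2"])
        assert cal_all.stage1.loc[0.22, "a1"] > 0

    def test_summary_text(self, probe22):
        data = _synthetic_calibration_data(probe22, 1.1, 3000.0, 0.75,
                                           noise=0.0, seed=2)
        cal = calibrate_constants(data, {0.22: probe22})
        text = cal.summary()
        assert "Stage 1" in text and "Stage 2" in text


class TestErrorStatistics:
    def test_perfect_predictions(self):
        r = np.array([1e-3, 2e-3, 5e-3])
        stats = error_statistics(r, r)
        assert stats["median"] == 0.0
        assert stats["max"] == 0.0

    def test_validity_filter(self):
        pred = np.array([1.0, 1.0, 2.0])
        ref = np.array([1.0, 2.0, 2.0])
        stats = error_statistics(pred, ref, musp_d=[0.05, 1.0, 1.0])
        assert stats["n"] == 2
        assert stats["median"] == 25.0

    def test_percent_scale(self):
        stats = error_statistics([1.1], [1.0])
        assert np.isclose(stats["median"], 10.0)
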