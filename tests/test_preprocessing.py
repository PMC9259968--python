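"""Temporal preprocessing: discard, motion QC, nuisance OLS, detrend, smooth."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import peraf
from peraf import MotionTrace, ValidationError
from peraf.preprocessing import detrend_bold
from conftest import make_bold


class TestDiscard:
    def test_default_discard_leaves_230_of_245(self, rng):
        bold = make_bold(rng.uniform(1, 2, (4, 4, 4, 245)))
        out = peraf.discard_initial_volumes(bold, 15)
        assert out.n_timepoints == 230
        assert out.grid_shape == (4, 4, 4)
        np.testing.assert_array_equal(out.data, bold.data[..., 15:])

    def test_zero_discard_is_identity(self, rng):
        bold = make_bold(rng.uniform(1, 2, (3, 3, 3, 20)))
        out = peraf.discard_initial_volumes(bold, 0)
        np.testing.assert_array_equal(out.data, bold.data)

    def test_discarding_whole_series_rejected(self, rng):
        bold = make_bold(rng.uniform(1, 2, (3, 3, 3, 10)))
        with pytest.raises(ValidationError):
            peraf.discard_initial_volumes(bold, 15)


class TestMotionExclusion:
    def test_still_subject_kept(self):
        tr = MotionTrace(np.zeros((50, 3)), np.zeros((50, 3)))
        assert peraf.motion_exclusion(tr) == (False, None)

    def test_translation_over_threshold_excluded_with_reason(self):
        t = np.zeros((50, 3))
        t[17, 1] = 1.6
        excluded, reason = peraf.motion_exclusion(MotionTrace(t, np.zeros((50, 3))))
        assert excluded
        assert "y" in reason and "17" in reason and "translation" in reason

    def test_exactly_at_threshold_kept(self):
        # the rule is a strict inequality: 1.5 mm itself passes
        t = np.zeros((50, 3))
        t[5, 0] = 1.5
        assert peraf.motion_exclusion(MotionTrace(t, np.zeros((50, 3))))[0] is False

    def test_rotation_over_threshold_excluded(self):
        r = np.zeros((50, 3))
        r[3, 2] = -1.7
        excluded, reason = peraf.motion_exclusion(MotionTrace(np.zeros((50, 3)), r))
        assert excluded and "rotation" in reason


class TestNuisanceRegression:
    def _setup(self, rng, nt=50):
        grid = (6, 6, 6)
        data = rng.uniform(900, 1100, (*grid, nt))
        wm = np.zeros(grid, bool)
        wm[:2, :2, :2] = True
        vent = np.zeros(grid, bool)
        vent[4:, 4:, 4:] = True
        return data, wm, vent

    def test_perfectly_explained_voxel_has_zero_peraf(self, rng):
        data, wm, vent = self._setup(rng)
        wm_mean = data[wm].mean(axis=0)
        data[3, 3, 3] = 2.0 * wm_mean + 50.0
        bold = make_bold(data)
        out = peraf.nuisance_regression(bold, [wm, vent], ["wm", "vent"])
        resid = out.data[3, 3, 3]
        assert np.allclose(resid, resid.mean(), atol=1e-8)
        assert peraf.peraf_series(resid) == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_regressor_leaves_series_unchanged(self):
        nt = 64
        grid = (3, 3, 3)
        t = np.arange(nt)
        data = np.tile(100 + np.sin(2 * np.pi * 5 * t / nt), (*grid, 1))
        reg_series = np.cos(2 * np.pi * 9 * t / nt)  # orthogonal on the grid
        mask = np.zeros(grid, bool)
        mask[0, 0, 0] = True
        data[0, 0, 0] = 100 + reg_series
        bold = make_bold(data)
        out = peraf.nuisance_regression(bold, [mask], ["reg"])
        np.testing.assert_allclose(out.data[1, 1, 1], data[1, 1, 1], atol=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        data, wm, vent = self._setup(rng)
        bold = make_bold(data)
        out = peraf.nuisance_regression(bold, [wm, vent], ["wm", "vent"])
        X = np.column_stack([np.ones(50), data[wm].mean(axis=0),
                             data[vent].mean(axis=0)])
        XtX_inv = np.linalg.inv(X.T @ X)
        for ijk in [(0, 3, 4), (5, 5, 0), (2, 2, 2)]:
            y = data[ijk]
            beta = XtX_inv @ X.T @ y
            expected = y - X @ beta + y.mean()
            np.testing.assert_allclose(out.data[ijk], expected, atol=1e-10)

    def test_voxel_mean_preserved(self, rng):
        data, wm, vent = self._setup(rng)
        out = peraf.nuisance_regression(make_bold(data), [wm, vent])
        np.testing.assert_allclose(out.data.mean(axis=3), data.mean(axis=3),
                                   atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self, rng):
        data, wm, vent = self._setup(rng)
        out = peraf.nuisance_regression(make_bold(data), [wm, vent])
        for mask in (wm, vent):
            reg = data[mask].mean(axis=0)
            reg = reg - reg.mean()
            resid = out.data[3, 1, 2] - out.data[3, 1, 2].mean()
            assert abs(resid @ reg) / (np.linalg.norm(reg) + 1e-30) < 1e-8

    def test_constant_regressor_rejected_by_name(self, rng):
        data, wm, _ = self._setup(rng)
        data[wm] = 1000.0
        with pytest.raises(ValidationError, match="white_matter"):
            peraf.nuisance_regression(make_bold(data), [wm], ["white_matter"])

    def test_collinear_regressors_rejected(self, rng):
        data, wm, _ = self._setup(rng)
        with pytest.raises(ValidationError, match="collinear"):
            peraf.nuisance_regression(make_bold(data), [wm, wm], ["a", "b"])


class TestLinearDetrend:
    def test_pure_line_becomes_constant_at_mean(self):
        t = np.arange(40, dtype=float)
        x = 3.0 + 0.5 * t
        out = peraf.linear_detrend(x)
        np.testing.assert_allclose(out, x.mean(), atol=1e-10)

    def test_idempotent(self, rng):
        x = rng.uniform(10, 20, 60)
        once = peraf.linear_detrend(x)
        np.testing.assert_allclose(peraf.linear_detrend(once), once, atol=1e-10)

    def test_line_plus_sinusoid_leaves_sinusoid(self):
        # a cosine symmetric about the series midpoint is orthogonal to
        # the centred linear trend, so detrending removes only the line
        n = 80
        t = np.arange(n, dtype=float)
        wave = np.cos(2 * np.pi * 4 * (t - (n - 1) / 2) / n)
        wave -= wave.mean()
        x = 5.0 + 0.3 * t + wave
        out = peraf.linear_detrend(x)
        np.testing.assert_allclose(out, x.mean() + wave, atol=1e-10)

    def test_refit_slope_is_zero(self, rng):
        x = peraf.linear_detrend(rng.uniform(0, 5, 50))
        t = np.arange(50) - 24.5
        assert abs((t @ (x - x.mean())) / (t @ t)) < 1e-10

    def test_bold_detrend_matches_series_detrend(self, rng):
        data = rng.uniform(50, 60, (3, 3, 3, 30))
        out = detrend_bold(make_bold(data))
        np.testing.assert_allclose(out.data[1, 2, 0],
                                   peraf.linear_detrend(data[1, 2, 0]),
                                   atol=1e-10)


class TestSmoothing:
    def _map(self, values, voxel_mm=2.0):
        affine = np.diag([voxel_mm] * 3 + [1.0])
        return peraf.AmplitudeMap(data=values, affine=affine, metric="PerAF",
                                  mask=np.ones(values.shape, bool))

    def test_zero_fwhm_is_identity(self, rng):
        m = self._map(rng.uniform(0, 1, (8, 8, 8)))
        out = peraf.gaussian_smooth_map(m, 0.0)
        np.testing.assert_array_equal(out.data, m.data)

    def test_interior_impulse_is_conserved(self):
        vals = np.zeros((15, 15, 15))
        vals[7, 7, 7] = 10.0
        out = peraf.gaussian_smooth_map(self._map(vals), 4.0)
        assert out.data.sum() == pytest.approx(10.0, rel=1e-10)
        assert out.data[7, 7, 7] < 10.0

    def test_uniform_map_unchanged(self):
        out = peraf.gaussian_smooth_map(self._map(np.full((8, 8, 8), 2.5)), 6.0)
        np.testing.assert_allclose(out.data, 2.5, rtol=1e-10)

    def test_negative_fwhm_rejected(self, rng):
        with pytest.raises(ValidationError):
            peraf.gaussian_smooth_map(self._map(rng.uniform(0, 1, (4, 4, 4))), -1.0)

    def test_matches_explicit_separable_convolution(self, rng):
        # independent oracle: build the truncated discrete Gaussian kernel
        # and convolve axis by axis with reflect padding
        vals = rng.uniform(0, 1, (10, 10, 10))
        fwhm, voxel = 5.0, 2.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / voxel
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        kernel = np.exp(-x ** 2 / (2 * sigma ** 2))
        kernel /= kernel.sum()

        def conv1d(arr, axis):
            # edge-repeating reflection ("symmetric" in numpy terms)
            padded = np.pad(arr, [(radius, radius) if a == axis else (0, 0)
                                  for a in range(3)], mode="symmetric")
            out = np.zeros_like(arr)
            for i, w in enumerate(kernel):
                sl = [slice(None)] * 3
                sl[axis] = slice(i, i + arr.shape[axis])
                out += w * padded[tuple(sl)]
            return out

        expected = vals
        for axis in range(3):
            expected = conv1d(expected, axis)
        out = peraf.gaussian_smooth_map(self._map(vals, voxel_mm=voxel), fwhm)
        np.testing.assert_allclose(out.data, expected, atol=1e-12)


class TestPreprocessSubject:
    def test_pipeline_order_and_report(self, rng):
        grid = (6, 6, 6)
        data = rng.uniform(900, 1100, (*grid, 40))
        wm = np.zeros(grid, bool)
        wm[0, 0, :3] = True
        bold = make_bold(data)
        out, report = peraf.preprocess_subject(
            bold, "sub-01", regressor_masks=[wm], regressor_names=["wm"],
            k_discard=5)
        assert out.n_timepoints == 35
        assert report.volumes_discarded == 5
        assert report.nuisance_regressors == ["wm"]
        assert not report.motion_excluded

    def test_excluded_subject_returns_none_with_rule(self, rng):
        data = rng.uniform(900, 1100, (4, 4, 4, 30))
        t = np.zeros((30, 3))
        t[10, 2] = 3.0
        out, report = peraf.preprocess_subject(
            make_bold(data), "sub-02", motion=MotionTrace(t, np.zeros((30, 3))),
            k_discard=2)
        assert out is None
        assert report.motion_excluded and "z" in report.exclusion_reason
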