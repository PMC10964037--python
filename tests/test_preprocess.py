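"""Preprocessing chain: volume discard, smoothing, band-pass, FD, scrubbing,
nuisance regression."""

import numpy as np
import pytest

from benfc.preprocess import (
    PreprocConfig,
    bandpass,
    discard_initial,
    framewise_displacement,
    friston24,
    preprocess_session,
    regress_nuisance,
    scrub_interpolate,
    smooth_gaussian,
)
from benfc.types import Bold4D, BrainMask, MotionParams, VolumeGrid


def make_bold(grid, data, tr=2.4):
    return Bold4D(grid, data, tr)


class TestDiscard:
    def test_217_minus_10_gives_207_with_motion_lockstep(self):
        grid = VolumeGrid.isotropic((3, 3, 3), 3.0)
        b = make_bold(grid, np.random.default_rng(0).standard_normal((3, 3, 3, 217)))
        mo = MotionParams(np.zeros((217, 3)), np.zeros((217, 3)))
        out, mo2 = discard_initial(b, 10, mo)
        assert out.n_volumes == 207
        assert mo2.n_volumes == 207

    def test_k_zero_is_identity(self, bold):
        out = discard_initial(bold, 0)
        assert np.array_equal(out.data, bold.data)

    def test_k_equal_t_raises(self, bold):
        with pytest.raises(ValueError):
            discard_initial(bold, bold.n_volumes)


class TestSmooth:
    def test_fwhm_zero_is_identity(self, bold):
        assert np.array_equal(smooth_gaussian(bold, 0.0).data, bold.data)

    def test_interior_impulse_mass_and_peak_match_closed_form(self):
        # hand-built separable discrete Gaussian as the independent oracle
        grid = VolumeGrid.isotropic((21, 21, 21), 3.0)
        data = np.zeros((*grid.dims, 2))
        data[10, 10, 10, :] = 1.0
        fwhm = 8.0
        out = smooth_gaussian(make_bold(grid, data), fwhm).data[..., 0]
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        sigma_vox = fwhm / (2 * np.sqrt(2 * np.log(2))) / 3.0
        radius = int(4 * sigma_vox + 0.5)  # matches truncate=4 support
        k = np.exp(-np.arange(-radius, radius + 1) ** 2 / (2 * sigma_vox**2))
        k /= k.sum()
        assert out[10, 10, 10] == pytest.approx(k[radius] ** 3, rel=1e-6)

    def test_constant_volume_unchanged(self):
        grid = VolumeGrid.isotropic((8, 8, 8), 3.0)
        data = np.full((*grid.dims, 2), 4.2)
        out = smooth_gaussian(make_bold(grid, data), 8.0).data
        assert np.allclose(out, 4.2, atol=1e-10)

    def test_negative_fwhm_raises(self, bold):
        with pytest.raises(ValueError):
            smooth_gaussian(bold, -1.0)


class TestBandpass:
    tr = 2.4

    def _sine(self, f, n=400):
        return np.sin(2 * np.pi * f * self.tr * np.arange(n))

    def test_passband_sine_survives(self):
        x = self._sine(0.05)
        y = bandpass(x, 0.01, 0.1, tr_s=self.tr)
        assert np.abs(y[50:-50]).max() >= 0.9 * np.abs(x).max()

    def test_stopband_sine_suppressed(self):
        x = self._sine(0.2)
        y = bandpass(x, 0.01, 0.1, tr_s=self.tr)
        assert np.abs(y[50:-50]).max() <= 0.1 * np.abs(x).max()

    def test_constant_series_becomes_zero(self):
        y = bandpass(np.full(100, 7.0), 0.01, 0.1, tr_s=self.tr)
        assert np.allclose(y, 0.0, atol=1e-8)

    def test_hi_at_nyquist_raises(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(50), 0.01, 0.25, tr_s=self.tr)


class TestFD:
    def test_zero_motion_gives_zero_fd(self):
        mo = MotionParams(np.zeros((10, 3)), np.zeros((10, 3)))
        assert np.array_equal(framewise_displacement(mo), np.zeros(10))

    def test_translation_step_formula(self):
        tr = np.zeros((5, 3))
        tr[3:, 0] = 0.1
        fd = framewise_displacement(MotionParams(tr, np.zeros((5, 3))))
        assert fd[3] == pytest.approx(0.1)
        assert fd[[0, 1, 2, 4]].sum() == 0

    def test_rotation_step_uses_head_radius(self):
        ro = np.zeros((5, 3))
        ro[2:, 1] = 0.01
        fd = framewise_displacement(MotionParams(np.zeros((5, 3)), ro))
        assert fd[2] == pytest.approx(0.5)  # 50 mm x 0.01 rad


class TestScrub:
    def test_no_flags_is_identity(self, bold):
        out, flagged = scrub_interpolate(bold, np.zeros(bold.n_volumes), 0.2)
        assert flagged == []
        assert np.array_equal(out.data, bold.data)

    def test_cubic_polynomial_reproduced_exactly(self):
        grid = VolumeGrid.isotropic((2, 2, 2), 3.0)
        t = np.arange(20, dtype=float)
        series = 0.5 * t**3 - 2 * t**2 + t - 3
        data = np.broadcast_to(series, (2, 2, 2, 20)).copy()
        fd = np.zeros(20)
        fd[7] = 1.0
        out, flagged = scrub_interpolate(make_bold(grid, data), fd, 0.2)
        assert flagged == [7]
        assert out.data[0, 0, 0, 7] == pytest.approx(series[7], abs=1e-9)

    def test_too_few_unflagged_raises(self):
        grid = VolumeGrid.isotropic((2, 2, 2), 3.0)
        data = np.random.default_rng(0).standard_normal((2, 2, 2, 6))
        fd = np.array([0, 1, 1, 0, 0, 1.0])
        with pytest.raises(ValueError):
            scrub_interpolate(make_bold(grid, data), fd, 0.2, max_flagged_frac=0.9)

    def test_majority_flagged_rejects_session(self):
        grid = VolumeGrid.isotropic((2, 2, 2), 3.0)
        data = np.random.default_rng(0).standard_normal((2, 2, 2, 10))
        fd = np.ones(10)
        fd[:4] = 0
        with pytest.raises(ValueError, match="rejected"):
            scrub_interpolate(make_bold(grid, data), fd, 0.2)


class TestNuisance:
    def test_confound_equal_to_voxel_series_zeroes_it(self, bold):
        conf = bold.data[0, 0, 0][:, None]
        out, dropped = regress_nuisance(bold, conf)
        assert dropped == []
        assert np.allclose(out.data[0, 0, 0], 0.0, atol=1e-10)

    def test_orthogonal_confound_only_removes_mean(self, grid):
        t = 40
        rng = np.random.default_rng(3)
        series = rng.standard_normal(t)
        series -= series.mean()
        conf = np.ones(t)
        conf[: t // 2] = -1.0  # orthogonalize against the series
        conf -= conf @ series / (series @ series) * series
        data = np.broadcast_to(series, (*grid.dims, t)).copy()
        out, _ = regress_nuisance(Bold4D(grid, data, 2.4), conf[:, None])
        assert np.allclose(out.data[0, 0, 0], series, atol=1e-8)

    def test_friston24_expansion_has_24_columns(self):
        mo = MotionParams(np.random.default_rng(0).standard_normal((30, 3)),
                          np.random.default_rng(1).standard_normal((30, 3)))
        assert friston24(mo).shape == (30, 24)

    def test_duplicate_column_dropped_and_reported(self, bold):
        c = np.random.default_rng(0).standard_normal(bold.n_volumes)
        out, dropped = regress_nuisance(bold, np.column_stack([c, c]))
        assert dropped == [1]

    def test_residuals_orthogonal_to_design(self, bold, rng):
        conf = rng.standard_normal((bold.n_volumes, 5))
        out, _ = regress_nuisance(bold, conf)
        resid = out.data.reshape(-1, bold.n_volumes)
        dots = resid @ conf / bold.n_volumes
        assert np.abs(dots).max() < 1e-8


class TestSessionChain:
    def test_manifest_records_order_and_flags(self, grid):
        rng = np.random.default_rng(0)
        t = 40
        bold = Bold4D(grid, rng.standard_normal((*grid.dims, t)), 2.4)
        tr = np.zeros((t, 3))
        tr[25, 0] = 0.5  # one spike -> FD > 0.2 at volumes 25 and 26
        mo = MotionParams(tr, np.zeros((t, 3)))
        mask = BrainMask(grid, np.ones(grid.dims, bool))
        cfg = PreprocConfig(n_discard=5, fwhm_mm=6.0)
        clean, manifest = preprocess_session(bold, mo, cfg, global_mask=mask)
        assert clean.n_volumes == t - 5
        assert manifest["order"] == ["discard", "smooth", "bandpass",
                                     "nuisance", "scrub"]
        assert manifest["flagged_volumes"] == [20, 21]  # after discard shift
        assert "global_signal" in manifest["confound_names"]
        assert np.isfinite(clean.data).all()
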