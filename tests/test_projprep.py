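"""Preprocessing chain: registration, flat-field, extraction, intensity
standardization, height tracking."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.ndimage import fourier_shift

from xstain import projprep as pp
from xstain.errors import (
    GeometryError,
    RegistrationError,
    StageError,
    WindowError,
)


def _textured(shape=(128, 128), seed=1):
    rng = np.random.default_rng(seed)
    return ndimage.gaussian_filter(rng.normal(0, 1, shape), 3) * 1000.0 + 8000.0


def _stack(frames, pixel_size=0.02):
    frames = np.asarray(frames, float)
    return pp.ProjectionStack(frames, np.arange(frames.shape[0], dtype=float),
                              pixel_size)


class TestRegistration:
    def test_integer_shift_recovered(self):
        base = _textured()
        moved = np.roll(np.roll(base, 3, axis=0), -2, axis=1)
        _, shifts = pp.register_stack(_stack([base, moved]))
        assert np.abs(shifts[1] - (3, -2)).max() <= 0.1

    def test_zero_shift_stack(self):
        base = _textured()
        _, shifts = pp.register_stack(_stack([base, base, base]))
        assert np.abs(shifts).max() <= 0.05

    def test_subpixel_shift_within_quarter_pixel(self):
        base = _textured()
        moved = np.fft.ifftn(fourier_shift(np.fft.fftn(base), (0.4, -0.4))).real
        _, shifts = pp.register_stack(_stack([base, moved]))
        assert np.abs(shifts[1] - (0.4, -0.4)).max() <= 0.25

    def test_constant_frame_rejected(self):
        base = _textured()
        with pytest.raises(RegistrationError):
            pp.register_stack(_stack([base, np.full_like(base, 5.0)]))


class TestFlatField:
    def _biased_stack(self, truth_value=9000.0, coeffs=(0.0, -0.02, 0.01, -0.05, -0.08)):
        shape = (64, 80)
        y, x = np.mgrid[0:shape[0], 0:shape[1]]
        xn = (x - (shape[1] - 1) / 2) / (shape[1] - 1)
        yn = (y - (shape[0] - 1) / 2) / (shape[0] - 1)
        b1, b2, b3, b4, b5 = coeffs
        Z = b1 + b2 * yn + b3 * xn + b4 * yn**2 + b5 * xn**2
        frames = np.repeat((truth_value * np.exp(Z))[None], 6, axis=0)
        return _stack(frames), Z

    def test_constant_stack_is_identity(self):
        st = _stack(np.full((6, 32, 40), 7000.0))
        out = pp.flatfield_correct(st)
        assert np.allclose(out.frames, st.frames)

    def test_known_bias_on_flat_truth_removed(self):
        st, _ = self._biased_stack()
        out = pp.flatfield_correct(st)
        for fr in out.frames:
            assert np.ptp(fr) / fr.mean() < 1e-2

    def test_near_idempotence(self):
        st, _ = self._biased_stack()
        once = pp.flatfield_correct(st)
        twice = pp.flatfield_correct(once)
        assert np.max(np.abs(twice.frames - once.frames) / once.frames) < 1e-3

    def test_nonpositive_median_pixel_rejected(self):
        frames = np.full((6, 16, 16), 100.0)
        frames[1:5, 3, 4] = -1.0
        with pytest.raises(ValueError, match=r"\(3, 4\)"):
            pp.flatfield_correct(_stack(frames))

    def test_needs_five_frames(self):
        with pytest.raises(Exception):
            pp.flatfield_correct(_stack(np.full((4, 8, 8), 5.0)))


class TestExtraction:
    def test_uniform_field(self):
        st = _stack(np.full((3, 80, 80), 7000.0))
        cs = pp.CrossSection(origin=(40, 40), depth_extent=(-0.2, 0.4), half_width=5)
        prof = pp.extract_profile(st, cs)
        assert prof.stage == "raw_w"
        assert np.allclose(prof.values, 7000.0)
        assert prof.depth_grid[0] == pytest.approx(-0.2)

    def test_out_of_bounds_footprint(self):
        st = _stack(np.full((3, 40, 40), 1.0))
        cs = pp.CrossSection(origin=(2, 20), depth_extent=(-0.3, 0.3))
        with pytest.raises(GeometryError):
            pp.extract_profile(st, cs)

    def test_half_width_zero_rejected(self):
        with pytest.raises(GeometryError):
            pp.CrossSection(origin=(0, 0), half_width=0)


class TestIntensityChain:
    def _profile(self, values, depths=None, stage="absorbance_u"):
        values = np.asarray(values, float)
        depths = np.asarray(depths if depths is not None
                            else np.linspace(-0.2, 0.5, values.shape[0]))
        return pp.IntensityProfile(depths, np.arange(values.shape[1], dtype=float),
                                   values, stage)

    def test_absorbance_complements_transmission(self):
        prof = self._profile(np.full((4, 2), 3580.0), stage="raw_w")
        u = pp.to_absorbance(prof)
        assert np.allclose(u.values, 6420.0)
        full = pp.to_absorbance(self._profile(np.full((4, 2), 10000.0), stage="raw_w"))
        assert np.allclose(full.values, 0.0)

    def test_absorbance_reverses_order(self):
        w = np.linspace(9000, 7000, 5)[None].repeat(4, 0)
        u = pp.to_absorbance(self._profile(w, stage="raw_w"))
        assert np.all(np.diff(u.values, axis=1) > 0)

    def test_stage_mismatch_rejected(self):
        prof = self._profile(np.zeros((3, 2)), stage="raw_w")
        with pytest.raises(StageError):
            pp.baseline_correct(prof)

    def test_constant_absorbance_baselines_to_minus_c(self):
        prof = self._profile(np.full((8, 3), 777.0),
                             depths=np.linspace(-0.18, 0.3, 8))
        ub = pp.baseline_correct(prof)
        assert np.allclose(ub.values, -777.0)

    def test_zero_baseline_is_identity(self):
        depths = np.linspace(-0.18, 0.3, 8)
        vals = np.where(depths[:, None] > 0, 500.0, 0.0) * np.ones((1, 3))
        ub = pp.baseline_correct(self._profile(vals, depths=depths))
        assert np.allclose(ub.values, vals)

    def test_drift_removed_in_solution_region(self):
        rng = np.random.default_rng(0)
        depths = np.linspace(-0.2, 0.5, 30)
        t = np.arange(20.0)
        drift = 50.0 * np.sin(t / 3.0)
        vals = np.where(depths[:, None] > 0, 800.0, 0.0) + drift[None, :]
        vals = vals + rng.normal(0, 1.0, vals.shape)
        ub = pp.baseline_correct(self._profile(vals, depths=depths))
        sol = ub.values[depths < -0.05]
        assert np.abs(sol.mean(axis=0) - sol.mean()).max() < 2.0

    def test_standardization_hand_values(self):
        # b_bar=1000, m=6420, a=0.61749 => u_min=397.778, u_ref=-3320.88,
        # u_norm=9740.88; u_b=2000 -> 0.54624
        prof = self._profile(np.full((4, 2), 2000.0), stage="baseline_corrected_ub")
        uh = pp.standardize(prof, b_bar=1000.0)
        assert uh.values[0, 0] == pytest.approx(0.54624, abs=1e-5)

    def test_standardization_affine_anchors(self):
        b_bar = 1000.0
        p = pp.StandardizationParams()
        q = (1 - 0.9) / 0.9
        u_min = b_bar - q * (p.m - b_bar)
        u_ref = u_min - p.a * (p.m - u_min)
        u_norm = (1 + p.a) * (p.m - u_min)
        zero = pp.standardize(self._profile(np.full((4, 2), u_ref),
                                            stage="baseline_corrected_ub"), b_bar=b_bar)
        one = pp.standardize(self._profile(np.full((4, 2), u_ref + u_norm),
                                           stage="baseline_corrected_ub"), b_bar=b_bar)
        assert np.allclose(zero.values, 0.0, atol=1e-12)
        assert np.allclose(one.values, 1.0)

    def test_solution_level_is_pinned(self):
        """Any constant solution level standardizes to the same u_hat
        (~0.4436), the property that anchors the concentration calibration."""
        for level in (-300.0, -800.0, -2000.0):
            prof = self._profile(np.full((8, 3), level),
                                 depths=np.linspace(-0.19, 0.3, 8),
                                 stage="baseline_corrected_ub")
            uh = pp.standardize(prof)
            assert np.allclose(uh.values, pp.solution_uhat(), atol=1e-12)

    def test_chain_is_affine_in_intensity_deviations(self):
        """Scaling all deviations from the baseline by k scales u_hat
        deviations from the solution level by k."""
        depths = np.linspace(-0.2, 0.5, 30)
        t = np.arange(6.0)
        dev = np.where(depths[:, None] > 0, 900.0, 0.0) * (1 + t[None, :] / 10)
        base = 300.0

        def run(k):
            w = 10000.0 - (base + k * dev)
            prof = pp.IntensityProfile(depths, t, w, "raw_w")
            return pp.standardize(pp.baseline_correct(pp.to_absorbance(prof)))

        u1, u2 = run(1.0), run(2.0)
        s = pp.solution_uhat()
        assert np.allclose(u2.values - s, 2.0 * (u1.values - s), atol=1e-9)

    def test_empty_baseline_window_rejected(self):
        prof = self._profile(np.zeros((4, 2)), depths=np.linspace(0.1, 0.4, 4))
        with pytest.raises(WindowError):
            pp.baseline_correct(prof)
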