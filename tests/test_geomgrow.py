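"""Geometry (curved-cap cylinder) and growth (monomolecular expansion) tests."""

import numpy as np
import pytest

from xstain.errors import FitError, GeometryError
from xstain.geomgrow import (
    GeometryModel,
    GrowthModel,
    curvature_radius,
    fit_growth,
    growth_curve,
    thickness,
    velocity_field,
)

PAPER_GROWTH = dict(a1=5.8697, a2=5.6924, tau=588.23)


class TestThickness:
    def test_apex_and_cap_base(self, geom):
        assert thickness(0.0, geom) == 0.0
        assert thickness(geom.H, geom) == pytest.approx(geom.R)
        assert thickness(geom.H + 1.0, geom) == geom.R

    def test_hand_value(self):
        # d(0.25) for R=4, H=0.5: 2*sqrt(0.5*4.25 - 0.0625)
        g = GeometryModel(R=4.0, H=0.5)
        assert thickness(0.25, g) == pytest.approx(2.87228, abs=1e-5)

    def test_negative_depth_rejected(self, geom):
        with pytest.raises(GeometryError):
            thickness(-0.1, geom)

    def test_matches_circle_chord_brute_force(self):
        """d(x) equals the chord of the curvature circle through apex and rim
        on random (R, H, x) triples."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            R = rng.uniform(0.5, 10.0)
            H = rng.uniform(0.05, R)
            x = rng.uniform(0.0, H)
            g = GeometryModel(R=R, H=H, L=max(3.0, H + 1), D=max(25.0, R + 1, H + 2))
            rc = curvature_radius(g)
            # circle center sits on the axis at depth rc below the apex;
            # chord at depth x has half-length sqrt(rc^2 - (rc - x)^2)
            chord = 2.0 * np.sqrt(max(rc**2 - (rc - x) ** 2, 0.0))
            assert thickness(x, g) == pytest.approx(chord, rel=1e-10, abs=1e-12)


class TestCurvature:
    def test_hand_value(self):
        assert curvature_radius(GeometryModel(R=4.0, H=0.5)) == pytest.approx(4.25)

    def test_hemispherical_cap(self):
        R = 3.0
        g = GeometryModel(R=R, H=R / 2.0)
        assert curvature_radius(g) == pytest.approx(R / 2.0)

    def test_flat_degenerate(self):
        with pytest.raises(GeometryError):
            curvature_radius(GeometryModel(flat=True))


class TestGrowthFit:
    def test_recovers_printed_parameters_to_4_sig_figs(self):
        t = np.arange(0.0, 1321.0, 15.0)
        g = growth_curve(t, GrowthModel(**PAPER_GROWTH))
        gm, se = fit_growth(g, t)
        assert gm.a1 == pytest.approx(PAPER_GROWTH["a1"], rel=5e-5)
        assert gm.a2 == pytest.approx(PAPER_GROWTH["a2"], rel=5e-5)
        assert gm.tau == pytest.approx(PAPER_GROWTH["tau"], rel=5e-5)
        assert se < 1e-8

    def test_initial_change_near_zero(self):
        gm = GrowthModel(**PAPER_GROWTH)
        assert growth_curve(0.0, gm) == pytest.approx(0.1773, abs=1e-4)

    def test_flat_series_degenerates_cleanly(self):
        gm, se = fit_growth(np.zeros(8), np.linspace(0, 100, 8))
        assert growth_curve(np.linspace(0, 100, 5), gm) == pytest.approx(0.0)
        assert se == 0.0

    def test_noisy_recovery_within_10_percent(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 1321.0, 15.0)
        g = growth_curve(t, GrowthModel(**PAPER_GROWTH))
        gm, _ = fit_growth(g + rng.normal(0, 0.2, t.size), t)
        assert gm.a1 == pytest.approx(PAPER_GROWTH["a1"], rel=0.10)

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_growth([0, 1, 2], [0, 1, 2])


class TestVelocityField:
    def test_zero_at_surface(self):
        gm = GrowthModel(**PAPER_GROWTH)
        assert velocity_field(0.0, 0.0, gm) == 0.0
        assert velocity_field(0.0, 500.0, gm) == 0.0

    def test_hand_value(self):
        gm = GrowthModel(**PAPER_GROWTH)
        assert velocity_field(1.0, 0.0, gm) == pytest.approx(-9.677e-5, rel=1e-3)

    def test_uniform_dilation_rate(self):
        gm = GrowthModel(**PAPER_GROWTH)
        x = np.array([0.2, 0.7, 1.9])
        v = velocity_field(x, 37.0, gm)
        assert np.allclose(v / x, v[0] / x[0])

    def test_characteristics_integrate_to_height_change(self):
        """A particle advected by v(x,t) ends at
        x0 * (1 + g(0)/100) / (1 + g(t)/100) (to first order in g/100,
        and exactly at x0 * exp(-(g(t) - g(0))/100))."""
        from scipy.integrate import solve_ivp

        gm = GrowthModel(**PAPER_GROWTH)
        x0 = 1.0
        sol = solve_ivp(lambda t, x: velocity_field(x[0], t, gm), (0, 1200.0),
                        [x0], rtol=1e-10, atol=1e-12)
        xT = sol.y[0, -1]
        g0, gT = growth_curve(0.0, gm), growth_curve(1200.0, gm)
        assert xT == pytest.approx(x0 * np.exp(-(gT - g0) / 100.0), rel=1e-8)
        assert xT == pytest.approx(x0 * (1 + g0 / 100) / (1 + gT / 100), rel=2e-3)
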