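"""Forward staining model: initial conditions, analytic oracles, conservation."""

import numpy as np
import pytest
from scipy.special import erfc

from xstain.errors import InvalidGridError
from xstain.geomgrow import thickness
from xstain.stainpde import (
    KineticParams,
    default_c0,
    initial_state,
    mass_balance,
    project_intensity,
    simulate,
)

GRID = np.linspace(0.0, 3.0, 301)


class TestInitialState:
    def test_solution_column_beyond_cap(self, kinetics, geom):
        y = initial_state(kinetics, geom, GRID)
        body = GRID >= geom.H
        assert np.allclose(y[body, 4], kinetics.C0 * (geom.D - geom.R))
        assert y[body, 4][0] == pytest.approx(21.0 * kinetics.C0)

    def test_no_bound_osmium_initially(self, kinetics, geom):
        y = initial_state(kinetics, geom, GRID)
        assert np.all(y[:, 1] == 0.0)

    def test_site_content_matches_quadrature(self, kinetics, geom):
        y = initial_state(kinetics, geom, GRID)
        got = np.trapezoid(y[:, 2], GRID)
        d = thickness(GRID, geom)
        d[0] = 0.0
        expected = kinetics.S0 * np.trapezoid(d, GRID)
        # s(0) is pinned to the boundary value 0; one node of difference
        assert got == pytest.approx(expected, rel=1e-3)

    def test_bad_grid_rejected(self, kinetics, geom):
        with pytest.raises(InvalidGridError):
            initial_state(kinetics, geom, np.array([0.0, 0.2, 0.1]))


class TestDiffusionOracle:
    def test_matches_erfc_profile(self, flat_geom):
        """Pure diffusion (no reactions, no flow) reproduces the
        semi-infinite-medium closed form erfc(x / (2 sqrt(De t)))."""
        kin = KineticParams(De=1e-3, kon=0.0, kunmask=0.0)
        times = np.array([0.0, 60.0, 300.0, 600.0])
        traj = simulate(kin, flat_geom, None, GRID, times)
        norm = traj.f / (kin.C0 * flat_geom.R)
        mask = GRID <= 2.0
        for j, t in enumerate(times[1:], start=1):
            ana = erfc(GRID[mask] / (2.0 * np.sqrt(kin.De * t)))
            assert np.max(np.abs(norm[mask, j] - ana)) <= 1e-2

    def test_tabulated_point(self, flat_geom):
        kin = KineticParams(De=1e-3, kon=0.0, kunmask=0.0)
        traj = simulate(kin, flat_geom, None, GRID, np.array([0.0, 600.0]))
        val = np.interp(0.775, GRID, traj.f[:, 1]) / (kin.C0 * flat_geom.R)
        assert val == pytest.approx(0.4795, abs=2e-3)


class TestConservation:
    def test_smb_pointwise_invariant_without_flow(self, kinetics, geom):
        times = np.arange(0.0, 601.0, 60.0)
        traj = simulate(kinetics, geom, None, GRID, times, rtol=1e-9, atol=1e-13)
        mb = mass_balance(traj, kinetics, geom)
        assert mb["smb_drift_rel"] < 1e-8

    def test_closed_system_total_conserved(self, kinetics, flat_geom):
        y0 = initial_state(kinetics, flat_geom, GRID)
        y0[:, 0] = kinetics.C0 * flat_geom.R * np.exp(-((GRID - 0.8) / 0.2) ** 2)
        traj = simulate(kinetics, flat_geom, None, GRID, np.arange(0.0, 601.0, 60.0),
                        bc_left="noflux", state0=y0, rtol=1e-9, atol=1e-13)
        mb = mass_balance(traj, kinetics, flat_geom)
        assert mb["fb_defect_rel"] < 1e-6

    def test_no_binding_means_no_bound_pool(self, geom):
        kin = KineticParams(kon=0.0)
        traj = simulate(kin, geom, None, GRID, np.array([0.0, 120.0, 300.0]))
        assert traj.b.max() == 0.0

    def test_no_unmasking_freezes_masked_pool(self, geom):
        kin = KineticParams(kunmask=0.0)
        traj = simulate(kin, geom, None, GRID, np.array([0.0, 120.0, 300.0]))
        assert np.max(np.abs(traj.m - traj.m[:, [0]])) == 0.0


class TestProjectIntensity:
    def test_zero_state_and_linearity(self, kinetics, geom):
        times = np.array([0.0, 60.0])
        traj = simulate(kinetics, geom, None, GRID, times)
        ih = project_intensity(traj, kinetics)
        traj.f *= 2.0
        traj.b *= 2.0
        traj.o *= 2.0
        assert np.allclose(project_intensity(traj, kinetics), 2.0 * ih)

    def test_solution_column_level_at_onset(self, kinetics, geom):
        """At t=0 the surface beam sees o + f = C0 D, i.e. the standardized
        solution level F_I2C * C0 * D (~0.4436 for the defaults)."""
        traj = simulate(kinetics, geom, None, GRID, np.array([0.0, 10.0]))
        ih = project_intensity(traj, kinetics)
        assert ih[0, 0] == pytest.approx(
            kinetics.F_I2C * kinetics.C0 * geom.D, rel=1e-12)
        assert ih[0, 0] == pytest.approx(0.44358, abs=1e-4)


class TestNumerics:
    def test_grid_refinement_convergence(self, kinetics, geom):
        """Halving the grid spacing changes the projected intensity by
        <0.5% on the fitting domain."""
        times = np.array([0.0, 300.0, 900.0])
        vals = {}
        for n in (151, 301):
            g = np.linspace(0.0, 3.0, n)
            traj = simulate(kinetics, geom, None, g, times)
            ih = project_intensity(traj, kinetics)
            x = np.arange(0.1, 0.701, 0.02)
            vals[n] = np.array([np.interp(x, g, ih[:, j]) for j in (1, 2)])
        rel = np.abs(vals[301] - vals[151]) / np.abs(vals[301])
        assert rel.max() < 5e-3

    def test_default_c0_matches_measured_solution_density(self):
        # ~82 nmol/mm^3 for a 2% solution in a 25 mm vial
        assert default_c0() * 1e6 == pytest.approx(82.7, abs=0.5)

    def test_saturation_plateau_rises_only_with_unmasking(self, geom):
        times = np.arange(0.0, 1201.0, 120.0)
        frozen = KineticParams(kunmask=0.0, M0=1.2e-4)
        slow = KineticParams(kunmask=15.0, M0=1.2e-4)
        x_probe = 0.3
        levels = {}
        for name, kin in (("frozen", frozen), ("slow", slow)):
            traj = simulate(kin, geom, None, GRID, times)
            ih = project_intensity(traj, kin)
            levels[name] = np.interp(x_probe, GRID, ih[:, -1]) - \
                np.interp(x_probe, GRID, ih[:, len(times) // 2])
        assert levels["slow"] > levels["frozen"] + 1e-3
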