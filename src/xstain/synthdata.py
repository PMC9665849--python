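"""Synthetic X-ray projection stacks and profile matrices with ground truth.

The generator emulates the statistical structure the preprocessing and
fitting chain assumes: a cylindrical tissue punch with a curved cortical cap
immersed in absorbing osmium solution, heavy-metal accumulation following
the forward staining model, monomolecular sample-height growth,
frame-to-frame translational jitter, a quadratic-in-log cone-beam intensity
bias, slow baseline drift, and additive detector noise (shot noise
optional).  Every generated artifact carries its ``GroundTruth`` so
downstream recovery tests can compare against the generating parameters.

Rendering choices (documented in the methods note): the punch is rendered
laterally uniform inside its footprint -- the profile along the depth axis
is the projected model intensity, emulating the central region of a wide
punch where the +-half-width averaging band sees constant thickness; shifts
are applied at render time in integer pixels by default so translated
scenes are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, InvalidGridError
from .geomgrow import GeometryModel, GrowthModel, growth_curve
from .projprep import ProjectionStack, StandardizationParams, solution_uhat
from .stainpde import KineticParams, project_intensity, simulate

__all__ = [
    "GroundTruth",
    "AcquisitionSpec",
    "model_uhat",
    "surface_row_trajectory",
    "generate_profile_data",
    "generate_projection_stack",
    "generate_concentration_series",
    "paper_growth",
]


def paper_growth() -> GrowthModel:
    """The fitted average expansion in buffered OsO4 (a1=5.8697%,
    a2=5.6924%, tau=588.23 min)."""
    return GrowthModel(a1=5.8697, a2=5.6924, tau=588.23)


@dataclass
class GroundTruth:
    """Generating parameters stored alongside every synthetic artifact."""

    kinetics: KineticParams = field(default_factory=KineticParams)
    geometry: GeometryModel = field(default_factory=GeometryModel)
    growth: GrowthModel | None = field(default_factory=paper_growth)
    shifts: np.ndarray | None = None      # per-frame (row, col) true shifts, px
    noise_sigma: float = 5.0              # additive detector noise, a.u.
    bias_coeffs: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)  # (b1, b2, b3, b4, b5)
    seed: int = 0
    solution_absorbance: float = 200.0    # raw absorbance of the solution, a.u.
    drift_amplitude: float = 10.0         # slow baseline drift amplitude, a.u.
    floor_absorbance: float = 3000.0      # vial floor / Sylgard band, a.u.
    shot_noise: bool = False

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if len(self.bias_coeffs) != 5:
            raise ValueError("bias_coeffs must have 5 entries (b1..b5)")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Scaled-down acquisition layout for synthetic recordings."""

    frame_interval: float = 30.0          # minutes
    n_frames: int = 46
    pixel_size: float = 0.02              # mm / pixel
    image_shape: tuple[int, int] = (256, 360)
    detector_full_scale: float = 10000.0
    sample_height: float = 3.2            # punch height above the vial bottom, mm
    floor_band: float = 0.3               # vial floor / Sylgard thickness, mm
    early_frames: int = 5                 # dense frames right after onset ...
    early_interval: float = 0.5           # ... at this spacing (minutes)

    def __post_init__(self):
        if self.frame_interval <= 0 or self.n_frames < 2 or self.pixel_size <= 0:
            raise InvalidGridError("need frame_interval > 0, n_frames >= 2, pixel_size > 0")

    def frame_times(self) -> np.ndarray:
        """Timestamps in minutes: a dense burst right after staining onset
        (the real recordings have frames every ~0.5-1 min, which the
        flat-field step relies on) followed by regular intervals covering
        the long incubation."""
        k = min(self.early_frames, self.n_frames)
        early = np.arange(k) * self.early_interval
        rest = early[-1] + np.arange(1, self.n_frames - k + 1) * self.frame_interval \
            if self.n_frames > k else np.empty(0)
        return np.concatenate([early, rest])


# ---------------------------------------------------------------------------
# forward model evaluation

def _simulate_uhat(truth: GroundTruth, times, n_nodes=301):
    geom = truth.geometry
    grid = np.linspace(0.0, geom.L, n_nodes)
    times = np.asarray(times, dtype=float)
    sim_times = times if times[0] == 0 else np.concatenate([[0.0], times])
    traj = simulate(truth.kinetics, geom, truth.growth, grid, sim_times)
    ihat = project_intensity(traj, truth.kinetics)
    if times[0] != 0:
        ihat = ihat[:, 1:]
    return grid, ihat


def model_uhat(truth: GroundTruth, depth_grid, time_grid, n_nodes=301):
    """Noiseless standardized intensity u_hat(x, t) of the forward model.

    Positive depths are interpolated from the staining simulation; negative
    depths (solution above the surface) take the constant solution level
    ``F_I2C * C0 * D``.
    """
    depth_grid = np.asarray(depth_grid, dtype=float)
    time_grid = np.asarray(time_grid, dtype=float)
    if np.any(np.diff(depth_grid) <= 0) or np.any(np.diff(time_grid) <= 0):
        raise InvalidGridError("depth and time grids must be strictly increasing")
    grid, ihat = _simulate_uhat(truth, time_grid, n_nodes)
    k = truth.kinetics
    sol_level = k.F_I2C * k.C0 * truth.geometry.D
    out = np.empty((depth_grid.size, time_grid.size))
    pos = depth_grid >= 0
    for j in range(time_grid.size):
        out[pos, j] = np.interp(depth_grid[pos], grid, ihat[:, j])
        out[~pos, j] = sol_level
    return out


def generate_profile_data(truth: GroundTruth, depth_grid, time_grid,
                          noise_sigma: float | None = None,
                          seed: int | None = None, n_nodes=301):
    """Standardized profile matrix u_hat + i.i.d. Gaussian noise, with truth.

    With ``noise_sigma = 0`` the output equals the forward model exactly.
    """
    sigma = truth.noise_sigma if noise_sigma is None else noise_sigma
    if sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    values = model_uhat(truth, depth_grid, time_grid, n_nodes=n_nodes)
    if sigma > 0:
        rng = np.random.default_rng(truth.seed if seed is None else seed)
        values = values + rng.normal(0.0, sigma, values.shape)
    from .projprep import IntensityProfile

    prof = IntensityProfile(np.asarray(depth_grid, float), np.asarray(time_grid, float),
                            values, "standardized_uhat")
    return prof, truth


# ---------------------------------------------------------------------------
# projection-stack rendering

def _design_u_norm(truth: GroundTruth, u_sol_raw, std: StandardizationParams):
    """The u_norm the preprocessing chain will reconstruct from this scene
    (noise-free): b_bar = -median_t(solution absorbance)."""
    b_bar = -float(np.median(u_sol_raw))
    q = (1.0 - std.saturation_uhat) / std.saturation_uhat
    u_min = b_bar - q * (std.m - b_bar)
    return (1.0 + std.a) * (std.m - u_min)


def _drift(truth: GroundTruth, times):
    if truth.drift_amplitude == 0:
        return np.zeros_like(times)
    period = max(times[-1], 1.0)
    return truth.drift_amplitude * np.sin(2.0 * np.pi * times / period)


def surface_row_trajectory(truth: GroundTruth, acq: AcquisitionSpec):
    """Integer surface row per frame: the sample height above the vial
    floor follows H0 * (1 + g(t)/100), rounded to pixels."""
    times = acq.frame_times()
    if truth.growth is None:
        h = np.full(times.size, acq.sample_height)
    else:
        h = acq.sample_height * (1.0 + growth_curve(times, truth.growth) / 100.0)
    ref_row = vial_floor_row(acq)
    return ref_row - np.round(h / acq.pixel_size).astype(int), times


def vial_floor_row(acq: AcquisitionSpec) -> int:
    """First image row of the vial floor / Sylgard band (the height
    reference)."""
    return acq.image_shape[0] - int(round(acq.floor_band / acq.pixel_size))


def _bias_field(coeffs, shape):
    """Quadratic log-intensity shading field, normalized to max 0 (the
    beam-axis reference); a global detector gain is not part of the bias."""
    rows, cols = shape
    y, x = np.mgrid[0:rows, 0:cols]
    xn = (x - (cols - 1) / 2.0) / max(cols - 1, 1)
    yn = (y - (rows - 1) / 2.0) / max(rows - 1, 1)
    b1, b2, b3, b4, b5 = coeffs
    Z = b1 + b2 * yn + b3 * xn + b4 * yn**2 + b5 * xn**2
    return Z - Z.max()


def generate_projection_stack(truth: GroundTruth, acq: AcquisitionSpec,
                              n_nodes=301):
    """Render a synthetic time-lapse projection stack with its ground truth.

    Each frame is ``detector_full_scale - u(x, y, t)`` multiplied by the
    exponential bias field, translated by the per-frame shift, plus noise.
    """
    rows, cols = acq.image_shape
    px = acq.pixel_size
    geom = truth.geometry
    rng = np.random.default_rng(truth.seed)

    shifts = truth.shifts
    if shifts is None:
        shifts = rng.integers(-5, 6, size=(acq.n_frames, 2)).astype(float)
        shifts[0] = 0.0
    shifts = np.asarray(shifts, dtype=float)
    truth = replace(truth, shifts=shifts)

    surface_rows, times = surface_row_trajectory(truth, acq)
    std = StandardizationParams()
    u_sol_raw = truth.solution_absorbance + _drift(truth, times)
    u_norm = _design_u_norm(truth, u_sol_raw, std)
    uhat_sol = solution_uhat(std)

    half_w_px = (geom.R / 2.0) / px
    ccen0 = (cols - 1) / 2.0
    min_surface = (surface_rows + shifts[:, 0]).min()
    if min_surface < 0.2 / px:
        raise GeometryError("image too small: need >= 200 um of solution above the surface")
    if ccen0 - half_w_px + shifts[:, 1].min() < 0 or \
            ccen0 + half_w_px + shifts[:, 1].max() > cols - 1:
        raise GeometryError("punch footprint exceeds the image laterally")

    grid, ihat = _simulate_uhat(truth, times, n_nodes)
    frames = np.empty((acq.n_frames, rows, cols))
    bias = np.exp(_bias_field(truth.bias_coeffs, (rows, cols)))
    row_idx = np.arange(rows)
    col_idx = np.arange(cols)
    floor_row = vial_floor_row(acq)
    for i, t in enumerate(times):
        srow = surface_rows[i] + shifts[i, 0]
        x_of_row = (row_idx - srow) * px
        uhat_col = np.interp(np.clip(x_of_row, 0.0, geom.L), grid, ihat[:, i])
        uhat_col = np.where(x_of_row < 0, uhat_sol, uhat_col)
        u = np.full((rows, cols), u_sol_raw[i])
        in_punch = np.abs(col_idx - (ccen0 + shifts[i, 1])) <= half_w_px
        u[:, in_punch] += ((uhat_col - uhat_sol) * u_norm)[:, None]
        in_floor = row_idx >= floor_row + shifts[i, 0]
        u[in_floor, :] = truth.floor_absorbance
        w = acq.detector_full_scale - u
        frames[i] = w * bias
    if truth.shot_noise:
        frames = rng.poisson(np.maximum(frames, 0.0)).astype(float)
    if truth.noise_sigma > 0:
        frames = frames + rng.normal(0.0, truth.noise_sigma, frames.shape)
    stack = ProjectionStack(frames, times.astype(float), px)
    return stack, truth


def generate_concentration_series(concentrations, acq: AcquisitionSpec,
                                  seed: int = 0, noise_sigma: float = 2.0,
                                  buffer_absorbance: float = 150.0):
    """Solution-only stacks whose mean absorbance is linear in concentration.

    A concentration of c % OsO4 adds ``F_I2C * C0(c) * D`` (converted to raw
    detector units) on top of the buffer absorbance; ``C0(c)`` scales the 2%
    reference concentration linearly.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    std = StandardizationParams()
    kin = KineticParams()
    geom = GeometryModel()
    times = acq.frame_times()
    u_norm = _design_u_norm(
        GroundTruth(noise_sigma=0.0, solution_absorbance=buffer_absorbance,
                    drift_amplitude=0.0),
        np.array([buffer_absorbance]), std)
    stacks = []
    for c in concentrations:
        c0_c = kin.C0 * c / 2.0
        u = buffer_absorbance + kin.F_I2C * c0_c * geom.D * u_norm
        w = acq.detector_full_scale - u
        frames = np.full((acq.n_frames, *acq.image_shape), w)
        if noise_sigma > 0:
            frames = frames + rng.normal(0.0, noise_sigma, frames.shape)
        stacks.append(ProjectionStack(frames, times.astype(float), acq.pixel_size))
    return stacks
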