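"""Inverse problem: fit the six staining-model parameters to a profile.

The free parameters are the effective diffusion coefficient ``De``, the
binding and unmasking rate constants ``kon`` and ``kunmask``, the initial
available and masked binding-site densities ``S0`` and ``M0``, and the
cap height ``H`` of the projection geometry.  The solution concentration
``C0`` is estimated directly from the solution window of the data; the
geometry constants ``R``, ``D``, ``L`` and the intensity scaling ``F_I2C``
are fixed.

The fit minimizes the squared misfit between the standardized data and
``F_I2C * (o + f + b)`` over a restricted space-time domain (default
x in [100, 700] um, t in [0, 1200] min) with a bounded trust-region
least-squares solver.  ``De``, ``kon`` and ``kunmask`` are optimized on a
log10 scale; ``S0``, ``M0`` and ``H`` linearly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, WindowError
from .geomgrow import GeometryModel, GrowthModel
from .projprep import IntensityProfile
from .stainpde import KineticParams, project_intensity, simulate

__all__ = [
    "FitDomain",
    "FitResult",
    "estimate_C0",
    "fit_kinetics",
    "residual_standard_error",
]


@dataclass(frozen=True)
class FitDomain:
    """Space-time domain over which residuals are formed."""

    depth_interval: tuple[float, float] = (0.100, 0.700)   # mm
    time_interval: tuple[float, float] = (0.0, 1200.0)     # min

    def __post_init__(self):
        if self.depth_interval[0] >= self.depth_interval[1] or \
                self.time_interval[0] >= self.time_interval[1]:
            raise WindowError("fit domain intervals must be nonempty")


@dataclass
class FitResult:
    """Outcome of the six-parameter kinetic fit."""

    params: KineticParams
    H: float
    geometry: GeometryModel
    se_res: float
    n_obs: int
    df: int
    converged: bool
    trace: list = field(default_factory=list)   # (n_eval, cost) pairs
    n_evals: int = 0


def estimate_C0(profile: IntensityProfile, D: float = 25.0,
                f_i2c: float = 214.6308,
                window: tuple[float, float] = (-0.150, -0.050),
                t_max: float = 1200.0) -> float:
    """Solution concentration from the standardized solution window:
    ``C0 = mean(u_hat over window, t <= t_max) / (D * F_I2C)`` (mmol/mm^3)."""
    profile.require_stage("standardized_uhat")
    dmask = (profile.depth_grid >= window[0]) & (profile.depth_grid <= window[1])
    tmask = profile.time_grid <= t_max
    if not dmask.any() or not tmask.any():
        raise WindowError("solution window or time range not covered by the data")
    return float(profile.values[np.ix_(dmask, tmask)].mean() / (D * f_i2c))


def residual_standard_error(observed, modeled, df: int) -> float:
    """``sqrt(sum((obs - mod)^2) / df)``."""
    observed = np.asarray(observed, float)
    modeled = np.asarray(modeled, float)
    if observed.shape != modeled.shape:
        raise FitError("observed and modeled matrices must be congruent")
    if df <= 0:
        raise FitError(f"degrees of freedom must be positive, got {df}")
    return float(np.sqrt(np.sum((observed - modeled) ** 2) / df))


DEFAULT_BOUNDS = {
    "De": (1e-5, 1e-1),        # mm^2/min
    "kon": (1e-2, 1e6),        # mm^3/(mmol*min)
    "kunmask": (1e-2, 1e6),
    "S0": (0.0, 2e-3),         # mmol/mm^3
    "M0": (0.0, 2e-3),
    "H": (0.05, 1.5),          # mm
}

_PARAM_ORDER = ("De", "kon", "kunmask", "S0", "M0", "H")
_LOG_PARAMS = ("De", "kon", "kunmask")


def _encode(p: dict) -> np.ndarray:
    return np.array([np.log10(p[k]) if k in _LOG_PARAMS else p[k]
                     for k in _PARAM_ORDER])


def _decode(x: np.ndarray) -> dict:
    return {k: (10.0 ** v if k in _LOG_PARAMS else float(v))
            for k, v in zip(_PARAM_ORDER, x)}


def fit_kinetics(
    profile: IntensityProfile,
    geom: GeometryModel,
    growth: GrowthModel | None,
    domain: FitDomain | None = None,
    init: dict | None = None,
    bounds: dict | None = None,
    *,
    C0: float | None = None,
    n_nodes: int = 301,
    f_i2c: float = 214.6308,
    xtol: float = 1e-10,
    ftol: float = 1e-10,
    max_nfev: int | None = None,
    verbose: int = 0,
) -> FitResult:
    """Bounded trust-region least-squares fit of (De, kon, kunmask, S0, M0, H).

    Each residual evaluation runs the forward staining simulation with the
    candidate parameters and cap height, interpolates the modeled intensity
    onto the data grid inside ``domain``, and returns the misfit against the
    standardized data.  Forward runs are memoized on the parameter vector.
    """
    profile.require_stage("standardized_uhat")
    domain = domain or FitDomain()
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    if C0 is None:
        C0 = estimate_C0(profile, D=geom.D, f_i2c=f_i2c,
                         t_max=domain.time_interval[1])

    dmask = (profile.depth_grid >= domain.depth_interval[0]) & \
            (profile.depth_grid <= domain.depth_interval[1])
    tmask = (profile.time_grid >= domain.time_interval[0]) & \
            (profile.time_grid <= domain.time_interval[1])
    if not dmask.any() or not tmask.any():
        raise WindowError("profile does not cover the fit domain")
    depths = profile.depth_grid[dmask]
    times = profile.time_grid[tmask]
    data = profile.values[np.ix_(dmask, tmask)]
    sim_times = times if times[0] == 0 else np.concatenate([[0.0], times])
    grid = np.linspace(0.0, geom.L, n_nodes)

    if init is None:
        init = {}
    defaults_init = {
        "De": 1e-3, "kon": 100.0, "kunmask": 100.0,
        "S0": 3e-4, "M0": 1e-4, "H": 0.5,
    }
    p0 = {**defaults_init, **init}
    for k in _PARAM_ORDER:
        lo, hi = bounds[k]
        p0[k] = min(max(p0[k], lo if k not in _LOG_PARAMS else max(lo, 1e-300)), hi)

    lo = np.array([np.log10(max(bounds[k][0], 1e-300)) if k in _LOG_PARAMS
                   else bounds[k][0] for k in _PARAM_ORDER])
    hi = np.array([np.log10(bounds[k][1]) if k in _LOG_PARAMS else bounds[k][1]
                   for k in _PARAM_ORDER])

    cache: dict[tuple, np.ndarray] = {}
    trace: list[tuple[int, float]] = []

    def forward(x):
        key = tuple(np.round(x, 12))
        if key in cache:
            return cache[key]
        p = _decode(x)
        kin = KineticParams(De=p["De"], kon=p["kon"], kunmask=p["kunmask"],
                            S0=p["S0"], M0=p["M0"], C0=C0, F_I2C=f_i2c)
        g = replace(geom, H=p["H"], flat=False)
        try:
            traj = simulate(kin, g, growth, grid, sim_times)
            ihat = project_intensity(traj, kin)
            if times[0] != 0:
                ihat = ihat[:, 1:]
            model = np.empty_like(data)
            for j in range(times.size):
                model[:, j] = np.interp(depths, grid, ihat[:, j])
        except Exception as exc:  # simulator failure -> large residual penalty
            warnings.warn(f"forward model failed at {p}: {exc}", stacklevel=2)
            model = np.full_like(data, 1e3)
        cache[key] = model
        return model

    def residuals(x):
        r = (forward(x) - data).ravel()
        trace.append((len(trace), float(np.sum(r * r))))
        return r

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        res = least_squares(
            residuals, _encode(p0), bounds=(lo, hi), method="trf",
            x_scale="jac", xtol=xtol, ftol=ftol, gtol=1e-12,
            max_nfev=max_nfev, verbose=verbose,
        )

    p = _decode(res.x)
    kin = KineticParams(De=p["De"], kon=p["kon"], kunmask=p["kunmask"],
                        S0=p["S0"], M0=p["M0"], C0=C0, F_I2C=f_i2c)
    n_obs = data.size
    df = n_obs - 6
    se = residual_standard_error(data, forward(res.x), df)
    return FitResult(
        params=kin, H=p["H"], geometry=replace(geom, H=p["H"], flat=False),
        se_res=se, n_obs=n_obs, df=df,
        converged=bool(res.status > 0), trace=trace, n_evals=len(trace),
    )
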