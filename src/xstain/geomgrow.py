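"""Tissue punch geometry and tissue expansion models.

The cortical biopsy punch is modeled as a cylinder of diameter ``R`` whose
top (cortical) surface is a curved cap of height ``H``.  The cap is the
spherical-cap-like surface obtained by passing a circle through the apex and
the cap rim; the chord of that circle at depth ``x`` is the projected tissue
thickness ``d(x)`` seen by a horizontal X-ray beam.

Tissue expansion during incubation is described by a monomolecular
(saturating) growth curve ``g(t) = a1 - a2*exp(-t/tau)`` in percent height
change, which induces a surface-anchored velocity field
``v(x, t) = -x * a2/(100*tau) * exp(-t/tau)`` used by the advection terms of
the staining model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, GeometryError

__all__ = [
    "GeometryModel",
    "GrowthModel",
    "thickness",
    "curvature_radius",
    "fit_growth",
    "growth_curve",
    "velocity_field",
]


@dataclass(frozen=True)
class GeometryModel:
    """Curved-cap cylinder geometry of a biopsy punch in a vial.

    Parameters
    ----------
    R : float
        Punch diameter in mm (the beam path through the cylindrical body).
    H : float
        Height of the curved cortical cap in mm.
    D : float
        Inner vial diameter in mm (beam path through the staining solution).
    L : float
        Maximum modeled depth in mm.
    flat : bool
        If True the cap is ignored and ``d(x) = R`` everywhere, which is the
        semi-infinite slab limit used by analytic diffusion oracles.
    """

    R: float = 4.0
    H: float = 0.5
    D: float = 25.0
    L: float = 3.0
    flat: bool = False

    def __post_init__(self):
        if not self.flat:
            if not (0 < self.H < self.L):
                raise GeometryError(f"need 0 < H < L, got H={self.H}, L={self.L}")
        if not (self.L <= self.D and self.R <= self.D):
            raise GeometryError("vial diameter D must bound both L and R")


@dataclass(frozen=True)
class GrowthModel:
    """Monomolecular growth of sample height, in percent of initial height.

    ``g(t) = a1 - a2 * exp(-t / tau)`` with ``g(inf) = a1`` and
    ``g(0) = a1 - a2``.  Units: ``a1``, ``a2`` in percent, ``tau`` in minutes.
    """

    a1: float
    a2: float
    tau: float

    def __post_init__(self):
        if self.tau <= 0:
            raise FitError(f"tau must be positive, got {self.tau}")


def growth_curve(t, growth: GrowthModel):
    """Percent height change ``g(t)`` at time ``t`` (minutes)."""
    t = np.asarray(t, dtype=float)
    return growth.a1 - growth.a2 * np.exp(-t / growth.tau)


def thickness(x, geom: GeometryModel):
    """Projected tissue thickness ``d(x)`` in mm at depth ``x`` (mm).

    ``d(x) = 2*sqrt((x/H)*(H^2 + R^2/4) - x^2)`` for ``0 <= x <= H`` and
    ``d(x) = R`` beyond the cap.  ``d(0) = 0`` (apex) and ``d(H) = R``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise GeometryError("thickness is defined for x >= 0 only")
    if geom.flat:
        return np.full_like(x, geom.R) if x.ndim else float(geom.R)
    cap = (geom.H**2 + geom.R**2 / 4.0) / geom.H
    inside = x <= geom.H
    arg = np.where(inside, x * cap - x**2, (geom.R / 2.0) ** 2)
    d = 2.0 * np.sqrt(np.maximum(arg, 0.0))
    d = np.where(inside, d, geom.R)
    return d if d.ndim else float(d)


def curvature_radius(geom: GeometryModel) -> float:
    """Radius of the circle approximating the cortical surface curvature.

    ``(1/(2H)) * (H^2 + R^2/4)``; equals ``R/2`` for a hemispherical cap
    (``H = R/2``).
    """
    if geom.flat or geom.H <= 0:
        raise GeometryError("curvature radius undefined for flat/degenerate cap")
    return (geom.H**2 + geom.R**2 / 4.0) / (2.0 * geom.H)


def velocity_field(x, t, growth: GrowthModel | None):
    """Expansion-induced flow velocity in mm/min at depth ``x`` and time ``t``.

    ``v(x,t) = -x * a2/(100*tau) * exp(-t/tau)`` in surface-anchored
    coordinates; linear in ``x`` (uniform dilation rate) and negative for
    ``x > 0`` during expansion.  ``growth=None`` means no deformation.
    """
    x = np.asarray(x, dtype=float)
    if growth is None:
        return np.zeros_like(x) if x.ndim else 0.0
    v = -x * growth.a2 / (100.0 * growth.tau) * np.exp(-np.asarray(t) / growth.tau)
    return v if np.ndim(v) else float(v)


def fit_growth(percent_change, times, sigma=None):
    """Least-squares fit of the monomolecular growth curve to a height series.

    Parameters
    ----------
    percent_change, times : array-like
        Percent height change and the matching times in minutes (>= 4 points).

    Returns
    -------
    (GrowthModel, float)
        Fitted model and the residual standard error with ``df = n - 3``.
    """
    y = np.asarray(percent_change, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.size != t.size or y.size < 4:
        raise FitError("growth fit needs >= 4 matched (t, percent) points")

    if np.ptp(y) < 1e-12:
        # Flat series: the saturating curve degenerates; report the constant
        # branch g(t) = a1 with a2 = 0.
        return GrowthModel(a1=float(y[0]) if abs(y[0]) > 0 else 0.0,
                           a2=0.0, tau=max(t[-1], 1.0)), 0.0

    # Initialization: a1 from the last observed value, a2 from the total rise,
    # tau from the time of half-rise.
    a1_0 = y[-1]
    a2_0 = y[-1] - y[0]
    half = y[0] + 0.5 * (y[-1] - y[0])
    idx = np.argmin(np.abs(y - half))
    tau_0 = max(t[idx], t[-1] / 10.0, 1e-6)
    tmax = float(t[-1])

    def model(tt, a1, a2, tau):
        return a1 - a2 * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model, t, y, p0=[a1_0, a2_0, tau_0],
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, 10.0 * tmax]),
            sigma=sigma, maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - optimizer diagnostics
        raise FitError(f"growth fit did not converge: {exc}") from exc

    gm = GrowthModel(a1=float(popt[0]), a2=float(popt[1]), tau=float(popt[2]))
    resid = y - model(t, *popt)
    df = y.size - 3
    se_res = float(np.sqrt(np.sum(resid**2) / df)) if df > 0 else 0.0
    return gm, se_res
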