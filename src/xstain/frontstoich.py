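"""Staining-front detection, the sqrt-time penetration law, and the
binding-site stoichiometry accounting.

A staining front is the moving boundary between osmium-saturated and
unstained tissue.  It is tracked per time point as the depth at which the
standardized intensity falls below a threshold, scanning inward from the
stained plateau; its trajectory follows the diffusive penetration rule of
thumb ``t ~ x^2`` (position ~ c * sqrt(t)).

The stoichiometry accounting converts literature phospholipid content into
a volumetric double-bond density and compares it with the fitted
binding-site density; all arithmetic is exact (rational) until the final
report.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, WindowError
from .projprep import IntensityProfile

__all__ = [
    "FrontTrajectory",
    "StoichiometryInputs",
    "detect_front",
    "fit_sqrt_law",
    "double_bond_density",
    "binding_site_ratio",
]


@dataclass
class FrontTrajectory:
    """Front position vs time, with the sqrt-law fit attached after fitting."""

    times: np.ndarray          # min
    positions: np.ndarray      # mm; NaN where no crossing exists
    threshold: float           # u_hat level defining the front
    fit_coefficient: float | None = None   # mm / min^p
    fit_exponent: float | None = None      # p (0.5 when fixed)
    se_res: float | None = None            # mm

    def valid(self):
        ok = np.isfinite(self.positions)
        return self.times[ok], self.positions[ok]


def detect_front(profile: IntensityProfile, threshold: float = 0.45) -> FrontTrajectory:
    """Depth of the staining front at each time.

    For each time the scan starts at the stained plateau (the per-time
    intensity maximum, which skips the thin-cap dip at the surface) and the
    front is the first depth where u_hat falls below ``threshold``, linearly
    interpolated between grid points.  Times without a crossing yield NaN.
    """
    profile.require_stage("standardized_uhat")
    pos_mask = profile.depth_grid > 0
    if not pos_mask.any():
        raise WindowError("profile has no positive depths")
    x = profile.depth_grid[pos_mask]
    vals = profile.values[pos_mask]
    positions = np.full(profile.time_grid.size, np.nan)
    any_crossing = False
    for j in range(profile.time_grid.size):
        v = vals[:, j]
        i0 = int(np.argmax(v))
        if v[i0] < threshold:
            continue  # never stained above threshold at this time
        below = np.nonzero(v[i0:] < threshold)[0]
        if below.size == 0:
            continue  # front beyond the profiled depth range
        i1 = i0 + below[0]
        x0, x1 = x[i1 - 1], x[i1]
        v0, v1 = v[i1 - 1], v[i1]
        positions[j] = x0 + (v0 - threshold) / (v0 - v1) * (x1 - x0)
        any_crossing = True
    if not any_crossing:
        raise FitError("threshold outside the profile's range at all times; no front")
    return FrontTrajectory(profile.time_grid.copy(), positions, threshold)


def fit_sqrt_law(ft: FrontTrajectory, free_exponent: bool = False) -> FrontTrajectory:
    """Least-squares fit of ``x = c * sqrt(t)`` (or ``c * t^p`` when free).

    Attaches the coefficient, exponent and the residual standard error in mm
    (df = n - number of fitted coefficients).
    """
    t, x = ft.valid()
    if t.size < 3:
        raise FitError("sqrt-law fit needs >= 3 valid (t, x) pairs")
    if free_exponent:
        ok = (t > 0) & (x > 0)
        lc, lp = np.polyfit(np.log(t[ok]), np.log(x[ok]), 1)[::-1]
        popt, _ = curve_fit(lambda tt, c, p: c * tt**p, t, x,
                            p0=[np.exp(lc), lp], maxfev=10000)
        c, p = float(popt[0]), float(popt[1])
        k = 2
    else:
        st = np.sqrt(t)
        c = float(np.sum(st * x) / np.sum(t))
        p = 0.5
        k = 1
    resid = x - c * t**p
    df = t.size - k
    se = float(np.sqrt(np.sum(resid**2) / df)) if df > 0 else 0.0
    ft.fit_coefficient = c
    ft.fit_exponent = p
    ft.se_res = se
    return ft


@dataclass(frozen=True)
class StoichiometryInputs:
    """Literature inputs for the double-bond / binding-site accounting."""

    phospholipid_per_gram: float = 56241.0   # nmol/g
    brain_mass: float = 0.427                # g
    brain_volume: float = 508.91             # mm^3
    bonds_per_lipid: float = 2.5
    site_density: float | None = None        # nmol/mm^3, e.g. fitted S0 (+ M0)

    def __post_init__(self):
        for name in ("phospholipid_per_gram", "brain_mass", "brain_volume",
                     "bonds_per_lipid"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def _frac(x: float) -> Fraction:
    return Fraction(repr(float(x)))


def double_bond_density(inputs: StoichiometryInputs, sig_figs: int = 4):
    """Volumetric double-bond density available for osmium binding.

    Returns ``(double_bonds, phospholipids)`` in nmol/mm^3:
    phospholipids = per-gram content * brain mass / brain volume, double
    bonds = phospholipids * bonds per lipid.  Rational arithmetic
    throughout; the phospholipid density is reported (and carried into the
    bond count) at ``sig_figs`` significant figures, so the defaults give
    47.19 and 47.19 * 2.5 = 117.975 nmol/mm^3.
    """
    if inputs.brain_volume == 0:
        raise ZeroDivisionError("brain volume must be nonzero")
    phos = _frac(inputs.phospholipid_per_gram) * _frac(inputs.brain_mass) \
        / _frac(inputs.brain_volume)
    if sig_figs is not None:
        phos = Fraction(f"{float(phos):.{sig_figs}g}")
    bonds = phos * _frac(inputs.bonds_per_lipid)
    return float(bonds), float(phos)


def binding_site_ratio(site_density: float, bond_density: float,
                       sig_figs: int = 4) -> float:
    """Ratio of fitted binding-site density to double-bond density,
    reported to ``sig_figs`` significant figures (default 4)."""
    if bond_density == 0:
        raise ZeroDivisionError("double-bond density must be nonzero")
    ratio = _frac(site_density) / _frac(bond_density)
    if ratio == 0:
        return 0.0
    return float(f"{float(ratio):.{sig_figs}g}")
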