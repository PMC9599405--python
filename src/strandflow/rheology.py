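"""Ostwald-de Waele (power-law) rheology.

The constitutive model is ``tau = k * gamma_dot**n`` with flow consistency
index ``k`` [Pa s^n] and flow behavior index ``n`` [-].  ``n < 1`` describes a
shear-thinning fluid.  Parameters are obtained from measured flow curves by an
ordinary least-squares line fit in (log gamma_dot, log tau) space restricted
to a stated shear-rate window; this closed-form fit is exact on noiseless
power-law data and unbiased for multiplicative log-normal noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InsufficientDataError

_log = logging.getLogger(__name__)

__all__ = [
    "PowerLawParams",
    "FlowCurve",
    "shear_stress",
    "apparent_viscosity",
    "fit_power_law",
    "points_in_range",
    "metzner_reed_reynolds",
]


@dataclass(frozen=True)
class PowerLawParams:
    """Power-law constitutive parameters and their validity window.

    Attributes
    ----------
    k : float
        Flow consistency index [Pa s^n], strictly positive.
    n : float
        Flow behavior index [-], in (0, 2].
    fit_range : tuple of float
        (min, max) shear rate [1/s] over which the parameters were fitted.
    """

    k: float
    n: float
    fit_range: tuple[float, float] = (0.1, 10.0)

    def __post_init__(self) -> None:
        if not np.isfinite(self.k) or self.k <= 0:
            raise DomainError(f"flow consistency index must be > 0, got k={self.k}")
        if not np.isfinite(self.n) or not 0 < self.n <= 2:
            raise DomainError(f"flow behavior index must lie in (0, 2], got n={self.n}")
        lo, hi = self.fit_range
        if not 0 < lo < hi:
            raise DomainError(f"fit_range must satisfy 0 < min < max, got {self.fit_range}")


@dataclass(frozen=True)
class FlowCurve:
    """A measured (or synthetic) flow curve: shear stress vs shear rate.

    Shear rates must be strictly increasing and all entries strictly positive;
    at least three points are required.
    """

    shear_rate: np.ndarray
    shear_stress: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.shear_rate, dtype=float)
        t = np.asarray(self.shear_stress, dtype=float)
        object.__setattr__(self, "shear_rate", g)
        object.__setattr__(self, "shear_stress", t)
        if g.ndim != 1 or t.ndim != 1 or g.size != t.size:
            raise DomainError("shear_rate and shear_stress must be 1-D arrays of equal length")
        if g.size < 3:
            raise InsufficientDataError(f"flow curve needs >= 3 points, got {g.size}")
        if np.any(g <= 0) or np.any(t <= 0):
            raise DomainError("flow-curve entries must be strictly positive")
        if np.any(np.diff(g) <= 0):
            raise DomainError("shear_rate must be strictly increasing")

    def __len__(self) -> int:
        return int(self.shear_rate.size)


def _as_positive(gamma_dot, name: str = "gamma_dot"):
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g <= 0) or not np.all(np.isfinite(g)):
        raise DomainError(f"{name} must be strictly positive and finite")
    return g


def shear_stress(params: PowerLawParams, gamma_dot):
    """Shear stress tau = k * gamma_dot**n [Pa]; strictly increasing in gamma_dot."""
    g = _as_positive(gamma_dot)
    out = params.k * g**params.n
    return float(out) if np.isscalar(gamma_dot) else out


def apparent_viscosity(params: PowerLawParams, gamma_dot):
    """Apparent viscosity eta = tau / gamma_dot = k * gamma_dot**(n-1) [Pa s].

    Strictly decreasing in gamma_dot for n < 1 (shear thinning).
    """
    g = _as_positive(gamma_dot)
    out = params.k * g ** (params.n - 1.0)
    return float(out) if np.isscalar(gamma_dot) else out


def points_in_range(curve: FlowCurve, fit_range: tuple[float, float]) -> np.ndarray:
    """Boolean mask of flow-curve points with shear rate inside [lo, hi]."""
    lo, hi = fit_range
    if not 0 < lo < hi:
        raise DomainError(f"fit_range must satisfy 0 < min < max, got {fit_range}")
    return (curve.shear_rate >= lo) & (curve.shear_rate <= hi)


def fit_power_law(curve: FlowCurve, fit_range: tuple[float, float] = (0.1, 10.0)) -> PowerLawParams:
    """Fit (k, n) by ordinary least squares in log-log space.

    Only points with shear rate inside ``fit_range`` are used; excluded points
    are counted and logged.  The slope of the line is ``n`` and the intercept
    is ``log k``.  On noiseless power-law data recovery is exact to numerical
    precision.

    Raises
    ------
    InsufficientDataError
        If fewer than three points fall inside the fit range.
    DomainError
        If the fitted slope falls outside the valid (0, 2] window.
    """
    mask = points_in_range(curve, fit_range)
    n_used = int(mask.sum())
    n_excluded = len(curve) - n_used
    if n_excluded:
        _log.info("fit_power_law: excluded %d of %d points outside fit range %s",
                  n_excluded, len(curve), fit_range)
    if n_used < 3:
        raise InsufficientDataError(
            f"need >= 3 points inside fit range {fit_range}, found {n_used}")
    x = np.log(curve.shear_rate[mask])
    y = np.log(curve.shear_stress[mask])
    slope, intercept = np.polyfit(x, y, 1)
    try:
        return PowerLawParams(k=float(np.exp(intercept)), n=float(slope),
                              fit_range=(float(fit_range[0]), float(fit_range[1])))
    except DomainError as exc:
        raise DomainError(
            f"fitted parameters invalid (raw slope n={slope:.6g}, "
            f"k={np.exp(intercept):.6g}): {exc}") from exc


def metzner_reed_reynolds(params: PowerLawParams, density: float,
                          mean_velocity: float, diameter: float) -> float:
    """Metzner-Reed generalized Reynolds number for power-law pipe flow.

    Re = rho * U**(2-n) * D**n / (k * ((3n+1)/(4n))**n * 8**(n-1)).
    Reduces to the classic rho*U*D/k for n = 1.  Values well below ~2100
    indicate laminar flow.
    """
    for name, val in (("density", density), ("mean_velocity", mean_velocity),
                      ("diameter", diameter)):
        if not np.isfinite(val) or val <= 0:
            raise DomainError(f"{name} must be strictly positive, got {val}")
    n, k = params.n, params.k
    return float(density * mean_velocity ** (2 - n) * diameter**n
                 / (k * ((3 * n + 1) / (4 * n)) ** n * 8 ** (n - 1)))
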