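"""Quantification of gradient profiles and core-shell cross-sections.

The transition descriptors (midpoint, 10-90 % width) are read off a monotone
envelope of the profile obtained by isotonic regression, restricted to the
rising (or falling) portion: a terminal decline past the plateau — the
signature of the fluorescence inner-filter artifact — is flagged but excluded
from the width, because it reflects the measurement, not the material
gradient.  All thresholds are relative to the profile span, so the metrics
are invariant to affine rescaling of the intensity axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InsufficientDataError
from .simulate import CrossSection, StrandProfile

__all__ = ["GradientMetrics", "compute_gradient_metrics", "core_shell_statistic"]


@dataclass(frozen=True)
class GradientMetrics:
    """Summary descriptors of a strand gradient profile.

    midpoint: position where the monotone envelope crosses 50 % of its span
    (NaN, with ``midpoint_defined=False``, for a constant profile);
    width_10_90: distance between the 10 % and 90 % span crossings;
    monotone_fraction: fraction of consecutive sample pairs ordered
    consistently with the overall direction; plateau/decline flags describe
    the rise-plateau-decline shape of inner-filter-affected fluorescence.
    """

    midpoint: float
    width_10_90: float
    monotone_fraction: float
    direction: int
    midpoint_defined: bool
    plateau_detected: bool
    plateau_interval: tuple[float, float] | None
    decline_detected: bool

    def to_dict(self) -> dict:
        return {
            "midpoint_m": self.midpoint,
            "width_10_90_m": self.width_10_90,
            "monotone_fraction": self.monotone_fraction,
            "direction": self.direction,
            "midpoint_defined": self.midpoint_defined,
            "plateau_detected": self.plateau_detected,
            "plateau_interval_m": list(self.plateau_interval) if self.plateau_interval else None,
            "decline_detected": self.decline_detected,
        }


def _pava_increasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators isotonic fit (unweighted, increasing)."""
    y = np.asarray(y, dtype=float)
    level = y.copy()
    weight = np.ones_like(y)
    n_blocks = 0
    vals = np.empty_like(y)
    wts = np.empty_like(y)
    sizes = np.empty(y.size, dtype=int)
    for i in range(y.size):
        vals[n_blocks] = level[i]
        wts[n_blocks] = weight[i]
        sizes[n_blocks] = 1
        n_blocks += 1
        while n_blocks > 1 and vals[n_blocks - 2] > vals[n_blocks - 1]:
            w = wts[n_blocks - 2] + wts[n_blocks - 1]
            vals[n_blocks - 2] = (wts[n_blocks - 2] * vals[n_blocks - 2]
                                  + wts[n_blocks - 1] * vals[n_blocks - 1]) / w
            wts[n_blocks - 2] = w
            sizes[n_blocks - 2] += sizes[n_blocks - 1]
            n_blocks -= 1
    return np.repeat(vals[:n_blocks], sizes[:n_blocks])


def compute_gradient_metrics(profile: StrandProfile, plateau_tol: float = 0.05,
                             min_plateau_samples: int = 2) -> GradientMetrics:
    """Compute transition midpoint, 10-90 % width, monotonicity and plateau flags.

    Requires at least four samples at strictly increasing positions.  The
    plateau is the maximal run of samples within ``plateau_tol`` of the
    profile extreme (relative to the span); samples after the plateau are
    excluded from the monotone envelope so a terminal inner-filter decline
    does not corrupt the width.
    """
    s = np.asarray(profile.positions, dtype=float)
    y = np.asarray(profile.values, dtype=float)
    if s.size < 4:
        raise InsufficientDataError(f"need >= 4 samples, got {s.size}")

    span_raw = float(y.max() - y.min())
    if span_raw == 0.0:
        return GradientMetrics(
            midpoint=float("nan"), width_10_90=0.0, monotone_fraction=1.0,
            direction=0, midpoint_defined=False, plateau_detected=True,
            plateau_interval=(float(s[0]), float(s[-1])), decline_detected=False)

    # overall direction from the sign of the position/value covariance
    direction = 1 if np.cov(s, y)[0, 1] >= 0 else -1
    # reflect decreasing profiles so the core works on rising data; the
    # reflection preserves widths and maps midpoints as s -> s[0]+s[-1]-s
    if direction < 0:
        s_w = (s[0] + s[-1]) - s[::-1]
        y_w = y[::-1]
    else:
        s_w, y_w = s, y

    diffs = np.diff(y)
    monotone_fraction = float(np.mean(direction * diffs >= 0))

    # plateau: maximal run of samples within plateau_tol*span of the maximum
    thresh = y_w.max() - plateau_tol * span_raw
    near_max = y_w >= thresh
    best_start = best_len = 0
    run_start = None
    for i, flag in enumerate(np.append(near_max, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = None
    plateau_detected = best_len >= min_plateau_samples
    plateau_end = best_start + best_len - 1 if best_len else int(np.argmax(y_w))
    decline_detected = bool(np.any(y_w[plateau_end + 1:] < thresh))

    # monotone envelope on the rising portion only (up to the plateau end)
    cut = plateau_end + 1
    env = _pava_increasing(y_w[:cut])
    s_env = s_w[:cut]
    span = float(env[-1] - env[0])
    if span == 0.0:
        midpoint, width = float("nan"), 0.0
        midpoint_defined = False
    else:
        levels = env[0] + np.array([0.1, 0.5, 0.9]) * span
        s10, s50, s90 = np.interp(levels, env, s_env)
        midpoint, width = float(s50), float(s90 - s10)
        midpoint_defined = True
        if direction < 0:
            midpoint = float(s[0] + s[-1] - midpoint)

    if plateau_detected:
        lo, hi = s_w[best_start], s_w[plateau_end]
        if direction < 0:
            lo, hi = s[0] + s[-1] - hi, s[0] + s[-1] - lo
        plateau_interval = (float(lo), float(hi))
    else:
        plateau_interval = None

    return GradientMetrics(
        midpoint=midpoint, width_10_90=width, monotone_fraction=monotone_fraction,
        direction=direction, midpoint_defined=midpoint_defined,
        plateau_detected=plateau_detected, plateau_interval=plateau_interval,
        decline_detected=decline_detected)


def core_shell_statistic(xs: CrossSection) -> float:
    """Signed core-shell statistic: mean C_A in the outer half minus the inner.

    The halves split the annuli at 50 % of cumulative weight (flux weights
    when the cross-section carries them, annulus areas otherwise), with the
    straddling annulus shared fractionally.  Positive values mean an A-rich
    shell around a B-rich core; the statistic is antisymmetric under A<->B
    label exchange (C -> 1 - C) and zero for a uniform section.
    """
    c = np.asarray(xs.C_A, dtype=float)
    if c.size < 2:
        raise InsufficientDataError("need at least 2 annuli")
    if xs.flux_weights is not None:
        w = np.asarray(xs.flux_weights, dtype=float).copy()
    else:
        edges = np.asarray(xs.r_edges, dtype=float)
        w = np.diff(edges**2)
    bad = ~np.isfinite(c) | (w <= 0)
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} empty/invalid annuli", stacklevel=2)
        c, w = c[~bad], w[~bad]
        if c.size < 2:
            raise InsufficientDataError("fewer than 2 valid annuli remain")
    w = w / w.sum()
    cum = np.cumsum(w)
    half = 0.5
    w_in = np.clip(np.minimum(cum, half) - (cum - w), 0.0, None)
    w_out = w - w_in
    if w_in.sum() == 0 or w_out.sum() == 0:
        raise DomainError("degenerate half-split of annulus weights")
    return float(np.sum(w_out * c) / w_out.sum() - np.sum(w_in * c) / w_in.sum())
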