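"""Forward model from labeled-material fraction to measured fluorescence.

``F(C) = alpha * C * exp(-beta * C)``: linear onset with gain ``alpha``,
self-attenuation with coefficient ``beta``.  For ``beta > 1`` the response
peaks inside (0, 1) at ``C = 1/beta`` and declines beyond it — the
rise/plateau/decline pattern produced by a concentration-dependent inner
filter effect in fluorescence sampling of a labeled gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["InnerFilterParams", "fluorescence_response"]


@dataclass(frozen=True)
class InnerFilterParams:
    """alpha: intensity per unit labeled fraction (> 0); beta: self-attenuation (>= 0)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise DomainError(f"alpha must be > 0, got {self.alpha}")
        if not np.isfinite(self.beta) or self.beta < 0:
            raise DomainError(f"beta must be >= 0, got {self.beta}")


def fluorescence_response(concentration, params: InnerFilterParams):
    """Measured intensity for labeled fractions in [0, 1] (arbitrary units)."""
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise DomainError("concentration must lie in [0, 1]")
    out = params.alpha * c * np.exp(-params.beta * c)
    return float(out) if np.ndim(concentration) == 0 else out
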