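"""Synthetic generators for every input the analysis pipeline consumes.

Flow curves carry multiplicative log-normal noise (stresses stay positive);
strand fluorescence samples carry additive Gaussian noise (instrument-like).
All stochastic output is a pure function of (config, seed); a seed is
mandatory whenever the configured noise level is nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError
from .flowfield import BlockFill, CartridgeGeometry, ExtrusionSettings
from .fluorescence import InnerFilterParams, fluorescence_response
from .rheology import FlowCurve, PowerLawParams
from .simulate import StrandProfile

__all__ = [
    "RheologySynthConfig",
    "StrandSynthConfig",
    "synth_flow_curve",
    "synth_strand_samples",
    "paper_defaults",
]


@dataclass(frozen=True)
class RheologySynthConfig:
    """True power-law parameters and sampling plan for a synthetic flow curve."""

    k: float = 148.89
    n: float = 0.2025
    shear_rate_range: tuple[float, float] = (0.1, 10.0)
    n_points: int = 50
    noise_sigma: float = 0.05   # std of the multiplicative log-normal noise

    def __post_init__(self) -> None:
        PowerLawParams(self.k, self.n, self.shear_rate_range)  # reuse validation
        if self.n_points < 3:
            raise DomainError("need at least 3 points")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class StrandSynthConfig:
    """Equal-distance fluorescence sampling plan along a printed strand.

    ``n_technical`` replicate measurements per spot times ``n_scaffolds``
    replicate scaffolds; ``noise_sigma`` is the additive noise std as a
    fraction of the peak noiseless intensity.
    """

    sampling_interval: float = 0.03   # m
    n_technical: int = 3
    n_scaffolds: int = 3
    inner_filter: InnerFilterParams = field(default_factory=lambda: InnerFilterParams(1.0, 2.5))
    noise_sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise DomainError("sampling_interval must be > 0")
        if self.n_technical < 1 or self.n_scaffolds < 1:
            raise DomainError("replicate counts must be >= 1")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")


def _rng_for(noise_sigma: float, seed: int | None) -> np.random.Generator | None:
    if noise_sigma == 0:
        return None
    if seed is None:
        raise DomainError("a seed is mandatory for stochastic output (noise_sigma > 0)")
    return np.random.default_rng(seed)


def synth_flow_curve(cfg: RheologySynthConfig, seed: int | None = None) -> FlowCurve:
    """tau_i = k * gdot_i**n * exp(eps_i), eps ~ N(0, sigma^2), gdot log-spaced."""
    lo, hi = cfg.shear_rate_range
    gdot = np.logspace(np.log10(lo), np.log10(hi), cfg.n_points)
    tau = cfg.k * gdot**cfg.n
    rng = _rng_for(cfg.noise_sigma, seed)
    if rng is not None:
        tau = tau * np.exp(rng.normal(0.0, cfg.noise_sigma, size=tau.shape))
    return FlowCurve(shear_rate=gdot, shear_stress=tau)


def synth_strand_samples(profile: StrandProfile, cfg: StrandSynthConfig,
                         seed: int | None = None) -> pd.DataFrame:
    """Replicated fluorescence samples at positions 0, d, 2d, ... along the strand.

    Returns a tidy frame with one row per (position, scaffold, technical
    replicate): columns ``position_m``, ``scaffold``, ``replicate``,
    ``concentration`` (noiseless interpolated labeled fraction) and
    ``intensity`` (inner-filter response plus additive noise).
    """
    length = float(profile.meta.get("strand_length_m", profile.positions[-1]))
    n_pos = int(np.floor(length / cfg.sampling_interval + 1e-9)) + 1
    if n_pos < 2:
        raise InsufficientDataError(
            f"strand of length {length} m too short for interval "
            f"{cfg.sampling_interval} m (need >= 2 positions)")
    positions = np.arange(n_pos) * cfg.sampling_interval
    conc = np.interp(positions, profile.positions, profile.values)
    base = fluorescence_response(conc, cfg.inner_filter)
    rng = _rng_for(cfg.noise_sigma, seed)
    sigma_abs = cfg.noise_sigma * (float(base.max()) if base.max() > 0 else 1.0)

    rows = []
    for i, (pos, c, f) in enumerate(zip(positions, conc, base)):
        for scaffold in range(1, cfg.n_scaffolds + 1):
            for rep in range(1, cfg.n_technical + 1):
                noise = rng.normal(0.0, sigma_abs) if rng is not None else 0.0
                rows.append((pos, scaffold, rep, c, f + noise))
    return pd.DataFrame(rows, columns=["position_m", "scaffold", "replicate",
                                       "concentration", "intensity"])


def paper_defaults() -> dict:
    """The default parameter set used throughout: fitted rheology, 3cc
    cartridge with a 20G outlet, 1:2 AB fill, 5 mm/s piston drive, 0.1 s
    steps and 20 mm/s print speed.  Wall mode defaults to slip (the
    simulation's stated outer boundary condition); no-slip is the variant
    that produces the core-shell segregation.
    """
    return {
        "params": PowerLawParams(k=148.89, n=0.2025, fit_range=(0.1, 10.0)),
        "geometry": CartridgeGeometry.from_gauge(20),
        "fill": BlockFill(block_a_length=15e-3, block_b_length=30e-3),
        "settings": ExtrusionSettings(piston_speed=5e-3, time_step=0.1,
                                      wall_mode="slip", print_speed=20e-3),
        "settings_no_slip": ExtrusionSettings(piston_speed=5e-3, time_step=0.1,
                                              wall_mode="no_slip", print_speed=20e-3),
        "pneumatic_pressure_bar": 0.1,   # run metadata only; drive is velocity-based
    }
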