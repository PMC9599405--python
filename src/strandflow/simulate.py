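"""Transient AB-block extrusion simulation (Lagrangian interface-marker engine).

The initial flat A/B interface is seeded with markers on a flux-uniform
radial grid (equal-flux annuli), so each marker represents an equal share of
the volumetric throughput, and is advected by the quasi-steady velocity
field.  Because the lubrication closure is self-similar, each marker stays on
a line of constant normalized radius and the concentration bookkeeping is
exact in volume: the material-A volume still inside the cartridge at any
instant is the area-weighted sum of the fluid volume ahead of each interface
marker, and the outlet concentration over an output interval is the ratio of
extruded-A volume to total extruded volume in that interval.

The piston phase ends when the piston crown reaches the cone entrance; by
default a drain phase follows in which the (conical) piston continues at the
same drive speed through the contraction, the flow rate shrinking with the
swept cross-section, until the cartridge is empty.  Markers overtaken by the
piston ride on its face and are expelled at the very end — the model's
rendering of residual first-material left at the walls being extruded last.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import DomainError
from .flowfield import (BlockFill, CartridgeGeometry, ExtrusionSettings,
                        VelocityField, build_velocity_field,
                        invert_flux_fraction)
from .rheology import PowerLawParams

__all__ = [
    "OutletSeries",
    "CrossSection",
    "StrandProfile",
    "ExtrusionResult",
    "simulate_extrusion",
    "outlet_to_strand",
    "residual_wall_fraction",
    "residual_after_piston_fraction",
]


@dataclass(frozen=True)
class OutletSeries:
    """Outlet flow/concentration time series on uniform output intervals.

    ``times`` are interval start times; ``C_A``/``C_B`` are interval-averaged
    flow-weighted concentration fractions (they sum to one); ``Q`` is the
    interval-mean volumetric flow rate.
    """

    times: np.ndarray          # s, interval left edges
    dts: np.ndarray            # s, interval widths (uniform except possibly last)
    Q: np.ndarray              # m^3/s, interval mean
    C_A: np.ndarray
    C_B: np.ndarray
    labels: tuple[str, str] = ("A", "B")
    piston_end_time: float = float("nan")
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.dts) == len(self.Q)
                == len(self.C_A) == len(self.C_B)):
            raise DomainError("outlet series columns must have equal length")
        if np.any(np.abs(self.C_A + self.C_B - 1.0) > 1e-9):
            raise DomainError("C_A + C_B must equal 1 at every sample")
        if np.any((self.C_A < -1e-12) | (self.C_A > 1 + 1e-12)):
            raise DomainError("concentrations must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def end_time(self) -> float:
        return float(self.times[-1] + self.dts[-1])

    def extruded_volumes(self) -> tuple[float, float]:
        """(volume of A, volume of B) extruded over the whole series [m^3]."""
        dv = self.Q * self.dts
        return float(np.sum(self.C_A * dv)), float(np.sum(self.C_B * dv))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "Q_m3_s": self.Q,
                             "C_A": self.C_A, "C_B": self.C_B})


@dataclass(frozen=True)
class CrossSection:
    """Per-annulus concentration of material A at the outlet plane at one time."""

    time: float
    r_edges: np.ndarray        # m, annulus edges partitioning [0, R_o]
    C_A: np.ndarray            # per annulus, in [0, 1]
    flux_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.r_edges) != len(self.C_A) + 1:
            raise DomainError("need len(r_edges) == len(C_A) + 1")
        if np.any((self.C_A < 0) | (self.C_A > 1)):
            raise DomainError("annulus concentrations must lie in [0, 1]")


@dataclass(frozen=True)
class StrandProfile:
    """Concentration (or intensity) vs arc length along the printed strand."""

    positions: np.ndarray      # m, strictly increasing, starting at 0
    values: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "values", v)
        if p.size != v.size:
            raise DomainError("positions and values must have equal length")
        if p.size and (abs(p[0]) > 1e-12 or np.any(np.diff(p) <= 0)):
            raise DomainError("positions must start at 0 and be strictly increasing")

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class ExtrusionResult:
    series: OutletSeries
    snapshots: list[CrossSection]
    meta: dict


def _piston_z(t, z_p0: float, v: float, l_out: float):
    return np.minimum(z_p0 + v * np.asarray(t, dtype=float), l_out)


def simulate_extrusion(geom: CartridgeGeometry, fill: BlockFill,
                       settings: ExtrusionSettings, params: PowerLawParams,
                       n_markers: int = 512,
                       snapshot_times: list[float] | None = None,
                       n_snapshot_annuli: int = 32,
                       drain: bool = True,
                       labels: tuple[str, str] = ("A", "B")) -> ExtrusionResult:
    """Run the transient AB-block extrusion and return the outlet series.

    Parameters
    ----------
    n_markers:
        Interface markers on the flux-uniform radial grid.
    snapshot_times:
        Times at which outlet cross-sections are emitted; defaults to
        0.25/0.5/0.75/0.95 of the total extrusion time.
    drain:
        If True (default) the conical-piston drain phase through the
        contraction is simulated so the full fill volume is extruded; if
        False the run stops when the piston reaches the cone entrance and
        the cone content is reported as un-extruded.
    labels:
        Material names, ``labels[0]`` being the outlet-side block.  The
        series columns ``C_A``/``C_B`` always refer to the materials *named*
        "A"/"B", so exchanging labels while reversing the fill is an exact
        bookkeeping symmetry.
    """
    fill.validate_against(geom)
    if sorted(labels) != ["A", "B"]:
        raise DomainError(f"labels must be a permutation of ('A', 'B'), got {labels}")
    if n_markers < 2:
        raise DomainError("need at least 2 markers")
    if n_snapshot_annuli < 1 or n_markers % n_snapshot_annuli:
        raise DomainError("n_snapshot_annuli must divide n_markers")

    field = build_velocity_field(geom, settings, params)
    v = settings.piston_speed
    dt_out = settings.time_step
    n, mode = params.n, settings.wall_mode
    rb = geom.barrel_radius
    l_out = geom.total_length
    q0 = field.flow_rate

    vol_first = np.pi * rb * rb * fill.block_a_length   # outlet-side block
    vol_second = np.pi * rb * rb * fill.block_b_length
    vol_fill = vol_first + vol_second
    z_p0 = geom.barrel_length - (fill.block_a_length + fill.block_b_length) \
        + geom.cone_volume / (np.pi * rb * rb)
    if z_p0 < -1e-12:
        raise DomainError("fill volume exceeds the cartridge capacity")
    z_p0 = max(z_p0, 0.0)
    z_int = geom.z_at_volume_from_outlet(vol_first)
    t_piston = (geom.barrel_length - z_p0) / v
    t_final = t_piston + (geom.cone_length / v if drain else 0.0)

    def vol_cum(t):
        """Cumulative extruded volume = fill volume minus volume ahead of the piston."""
        return vol_fill - np.asarray(geom.volume_to_outlet(_piston_z(t, z_p0, v, l_out)))

    def q_factor(t):
        """Q(t)/Q0: unity in the barrel, swept-area ratio in the drain phase."""
        rp = np.asarray(geom.radius(_piston_z(t, z_p0, v, l_out)))
        return (rp / rb) ** 2

    # --- marker seeding on the flux-uniform grid -------------------------
    psi_edges = np.linspace(0.0, 1.0, n_markers + 1)
    psi_mid = 0.5 * (psi_edges[:-1] + psi_edges[1:])
    xi_edges = invert_flux_fraction(psi_edges, n, mode)
    xi_mid = invert_flux_fraction(psi_mid, n, mode)
    area_w = np.diff(xi_edges**2)            # sums to 1 exactly
    z = np.full(n_markers, z_int)
    r = xi_mid * float(np.asarray(geom.radius(z_int)))
    clock = np.zeros(n_markers)
    exited = np.zeros(n_markers, dtype=bool)
    caught = np.zeros(n_markers, dtype=bool)
    t_exit = np.full(n_markers, np.inf)
    first_catch = np.inf

    # --- output grid -----------------------------------------------------
    n_whole = int(np.floor(t_final / dt_out + 1e-9))
    edges = np.arange(n_whole + 1) * dt_out
    if edges[-1] < t_final - 1e-9 * dt_out:
        edges = np.append(edges, t_final)
    a_rem = np.empty(edges.size)
    a_rem[0] = vol_first   # exact by construction of z_int and the area weights

    h_cap = l_out / 150.0
    h_floor = geom.outlet_radius / 8.0
    tiny = 1e-300

    def rhs(rr, zz, tt):
        u_r, u_z = field._velocity_unchecked(np.maximum(rr, 0.0), np.clip(zz, 0.0, l_out))
        q = q_factor(tt)
        return u_r * q, u_z * q

    for i_edge in range(1, edges.size):
        t1 = edges[i_edge]
        # advance active markers to t1 with per-marker adaptive RK4 steps
        for _ in range(100_000):
            go = ~exited & ~caught & (clock < t1 - 1e-12)
            if not go.any():
                break
            idx = np.where(go)[0]
            rr, zz, tt = r[idx], z[idx], clock[idx]
            _, u_z0 = rhs(rr, zz, tt)
            h_z = np.maximum(np.minimum(h_cap, 0.1 * (l_out - zz)), h_floor)
            # land steps exactly on the barrel/cone kink so no RK4 step
            # straddles the slope discontinuity of R(z)
            below = zz < geom.barrel_length - 1e-15
            h_z = np.where(below, np.minimum(h_z, geom.barrel_length - zz), h_z)
            dt = np.minimum(t1 - tt, h_z / np.maximum(u_z0, tiny))
            k1r, k1z = rhs(rr, zz, tt)
            k2r, k2z = rhs(rr + 0.5 * dt * k1r, zz + 0.5 * dt * k1z, tt + 0.5 * dt)
            k3r, k3z = rhs(rr + 0.5 * dt * k2r, zz + 0.5 * dt * k2z, tt + 0.5 * dt)
            k4r, k4z = rhs(rr + dt * k3r, zz + dt * k3z, tt + dt)
            r_new = rr + dt / 6.0 * (k1r + 2 * k2r + 2 * k3r + k4r)
            z_new = zz + dt / 6.0 * (k1z + 2 * k2z + 2 * k3z + k4z)
            t_new = tt + dt
            # outlet crossing: interpolate the last segment onto the exit plane
            crossed = z_new >= l_out - 1e-15
            if crossed.any():
                ci = idx[crossed]
                frac = (l_out - zz[crossed]) / np.maximum(z_new[crossed] - zz[crossed], tiny)
                t_exit[ci] = tt[crossed] + frac * dt[crossed]
                exited[ci] = True
                z[ci] = l_out
                clock[ci] = t1
            # piston catch: marker overtaken by the advancing crown
            keep = ~crossed
            ki = idx[keep]
            zp_now = _piston_z(t_new[keep], z_p0, v, l_out)
            hit = z_new[keep] <= zp_now
            if hit.any():
                hi = ki[hit]
                caught[hi] = True
                z[hi] = zp_now[hit]
                clock[hi] = t1
                # conservative onset: the catch happened somewhere inside the
                # substep, so record its start time
                first_catch = min(first_catch, float(np.min(tt[keep][hit])))
            ok = ki[~hit]
            z_ok = z_new[keep][~hit]
            # nudge markers that landed exactly on the barrel/cone kink so the
            # next step's stages see the cone-side slope consistently
            on_kink = np.abs(z_ok - geom.barrel_length) < 1e-15
            z_ok[on_kink] = np.nextafter(geom.barrel_length, l_out)
            z[ok] = z_ok
            r[ok] = np.maximum(r_new[keep][~hit], 0.0)
            clock[ok] = t_new[keep][~hit]
        else:  # pragma: no cover - safety net
            raise RuntimeError("marker advance failed to reach the output edge")
        zp1 = float(_piston_z(t1, z_p0, v, l_out))
        z[caught] = zp1
        clock[caught & ~exited] = t1
        z_eff = np.where(exited, l_out, np.maximum(z, zp1))
        a_rem[i_edge] = float(np.sum(area_w * np.asarray(geom.volume_to_outlet(z_eff))))

    if drain:
        t_exit[~exited] = t_final
    # markers still inside with drain=False keep t_exit = inf (still delivering A)

    a_ext = vol_first - a_rem
    dv = np.diff(vol_cum(edges))
    if np.any(dv <= 0):
        raise RuntimeError("non-positive extruded volume in an output interval")
    c_first = np.clip(np.diff(a_ext) / dv, 0.0, 1.0)
    c_second = 1.0 - c_first
    c_a, c_b = (c_first, c_second) if labels[0] == "A" else (c_second, c_first)
    series = OutletSeries(
        times=edges[:-1], dts=np.diff(edges), Q=dv / np.diff(edges),
        C_A=c_a, C_B=c_b, labels=labels, piston_end_time=t_piston,
        meta={
            "wall_mode": mode,
            "drain": drain,
            "flow_rate_barrel_m3_s": q0,
            "extruded_first_m3": float(a_ext[-1]),
            "extruded_total_m3": float(vol_cum(edges[-1])),
            "residual_first_in_domain_m3": float(a_rem[-1]),
            "fill_volumes_m3": (vol_first, vol_second),
            "interface_z_m": z_int,
            "piston_start_z_m": z_p0,
            "first_catch_time_s": None if not np.isfinite(first_catch) else first_catch,
            "n_markers": n_markers,
        })

    # --- outlet cross-section snapshots ---------------------------------
    if snapshot_times is None:
        snapshot_times = [f * t_final for f in (0.25, 0.5, 0.75, 0.95)]
    group = n_markers // n_snapshot_annuli
    edge_idx = np.arange(0, n_markers + 1, group)
    r_out_edges = xi_edges[edge_idx] * geom.outlet_radius
    snapshots = []
    for ts in snapshot_times:
        if not 0 <= ts <= t_final + 1e-9:
            raise DomainError(f"snapshot time {ts} outside [0, {t_final}]")
        delivering = (t_exit > ts).astype(float).reshape(n_snapshot_annuli, group)
        c = delivering.mean(axis=1)
        if labels[0] != "A":
            c = 1.0 - c
        snapshots.append(CrossSection(
            time=float(ts), r_edges=r_out_edges, C_A=c,
            flux_weights=np.full(n_snapshot_annuli, 1.0 / n_snapshot_annuli)))

    meta = {"piston_end_time_s": t_piston, "end_time_s": t_final,
            "marker_exit_times_s": t_exit, "marker_flux_fractions": psi_mid,
            **series.meta}
    return ExtrusionResult(series=series, snapshots=snapshots, meta=meta)


def outlet_to_strand(series: OutletSeries, print_speed: float) -> StrandProfile:
    """Map the outlet time series onto arc length along the printed strand.

    ``s_i = print_speed * t_i``; concentrations carry over unchanged.  The
    deposited volume per unit strand length (Q / print_speed) is reported as
    metadata.
    """
    if not np.isfinite(print_speed) or print_speed <= 0:
        raise DomainError(f"print_speed must be > 0, got {print_speed}")
    if len(series) == 0:
        raise DomainError("outlet series is empty")
    return StrandProfile(
        positions=print_speed * series.times,
        values=series.C_A.copy(),
        meta={
            "strand_length_m": print_speed * series.end_time,
            "volume_per_length_m2": float(np.mean(series.Q)) / print_speed,
            "print_speed_m_s": print_speed,
            "labels": series.labels,
        })


def residual_wall_fraction(series: OutletSeries, threshold: float = 0.01) -> float:
    """Fraction of material A extruded at or after C_A first reaches ``threshold``.

    Returns 0 (with a warning) if the series never falls to the threshold.
    A degenerate plug extrusion has a step-shaped series and returns 0.
    """
    if not 0 < threshold <= 1:
        raise DomainError(f"threshold must lie in (0, 1], got {threshold}")
    da = series.C_A * series.Q * series.dts
    total = float(da.sum())
    if total <= 0:
        return 0.0
    below = np.where(series.C_A <= threshold)[0]
    if below.size == 0:
        warnings.warn(f"C_A never fell to threshold {threshold}; returning 0",
                      stacklevel=2)
        return 0.0
    return float(da[below[0]:].sum() / total)


def residual_after_piston_fraction(series: OutletSeries) -> float:
    """Fraction of extruded material A that leaves after the piston phase ends.

    This is the drain-phase share of A — nonzero in no-slip mode, where
    slow near-wall first material is expelled only while the conical piston
    sweeps the contraction; identically zero for plug (slip) extrusion of a
    flat interface that clears the cartridge earlier.
    """
    da = series.C_A * series.Q * series.dts
    total = float(da.sum())
    if total <= 0:
        return 0.0
    late = series.times + series.dts > series.piston_end_time + 1e-12
    return float(da[late].sum() / total)
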