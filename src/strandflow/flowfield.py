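"""Axisymmetric cartridge geometry and the quasi-steady velocity-field model.

The cartridge is a straight barrel of radius ``R_b`` followed by a linear
conical taper to the outlet radius ``R_o``; the axial coordinate ``z`` runs
from the barrel entrance (z = 0) to the outlet plane.  The piston pushes a
volumetric flow ``Q = v * pi * R_b**2`` through every cross-section.  The
axial velocity is locally fully developed (lubrication closure),

    u_z(r, z) = U(z) * phi(r / R(z)),    U(z) = Q / (pi * R(z)**2),

with a plug shape ``phi = 1`` under free-slip walls and the standard
power-law tube profile under no-slip walls.  The radial component follows
from incompressibility, which for this self-similar closure makes each
streamline a line of constant normalized radius ``xi = r / R(z)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .errors import ConvergenceError, DomainError, StateError
from .rheology import PowerLawParams

__all__ = [
    "GAUGE_INNER_DIAMETER_M",
    "CartridgeGeometry",
    "BlockFill",
    "ExtrusionSettings",
    "VelocityField",
    "Streamline",
    "profile_shape",
    "flux_fraction",
    "invert_flux_fraction",
    "build_velocity_field",
    "streamline",
]

# Industry-convention needle inner diameters (not paper-reported values).
GAUGE_INNER_DIAMETER_M = {14: 1.60e-3, 16: 1.19e-3, 20: 0.603e-3}

WALL_MODES = ("slip", "no_slip")


@dataclass(frozen=True)
class CartridgeGeometry:
    """Barrel + conical contraction, all lengths in metres.

    ``outlet_radius == barrel_radius`` is permitted as the degenerate
    straight-tube geometry used by analytic-limit tests.
    """

    barrel_radius: float
    barrel_length: float
    cone_length: float
    outlet_radius: float

    def __post_init__(self) -> None:
        if not 0 < self.outlet_radius <= self.barrel_radius:
            raise DomainError(
                f"need 0 < outlet_radius <= barrel_radius, got "
                f"R_o={self.outlet_radius}, R_b={self.barrel_radius}")
        if self.barrel_length <= 0 or self.cone_length <= 0:
            raise DomainError("barrel_length and cone_length must be > 0")

    @classmethod
    def from_gauge(cls, needle_gauge: int, barrel_radius: float = 4.8e-3,
                   barrel_length: float = 55e-3, cone_length: float = 8e-3
                   ) -> "CartridgeGeometry":
        """Default 3cc-cartridge geometry with a gauge-preset outlet diameter."""
        try:
            d = GAUGE_INNER_DIAMETER_M[int(needle_gauge)]
        except KeyError:
            raise DomainError(
                f"no preset for gauge {needle_gauge}; known: "
                f"{sorted(GAUGE_INNER_DIAMETER_M)}") from None
        return cls(barrel_radius, barrel_length, cone_length, d / 2)

    @property
    def total_length(self) -> float:
        return self.barrel_length + self.cone_length

    @cached_property
    def cone_volume(self) -> float:
        rb, ro = self.barrel_radius, self.outlet_radius
        return np.pi * self.cone_length / 3.0 * (rb * rb + rb * ro + ro * ro)

    def radius(self, z):
        """Local radius R(z); clamped to R_b before the barrel and R_o past the outlet."""
        z = np.asarray(z, dtype=float)
        frac = np.clip((z - self.barrel_length) / self.cone_length, 0.0, 1.0)
        r = self.barrel_radius - (self.barrel_radius - self.outlet_radius) * frac
        return r if r.ndim else float(r)

    def dradius_dz(self, z):
        """dR/dz: 0 in the barrel, constant negative slope in the cone."""
        z = np.asarray(z, dtype=float)
        slope = -(self.barrel_radius - self.outlet_radius) / self.cone_length
        out = np.where((z > self.barrel_length) & (z <= self.total_length), slope, 0.0)
        return out if out.ndim else float(out)

    def volume_to_outlet(self, z):
        """Fluid volume between axial position z and the outlet plane."""
        z = np.asarray(z, dtype=float)
        zc = np.clip(z, 0.0, self.total_length)
        rb, ro, lc = self.barrel_radius, self.outlet_radius, self.cone_length
        # cone part: pi * integral of R(z)^2 dz from max(z, L_bar) to L_out
        if rb == ro:
            v_cone = np.pi * rb * rb * (self.total_length - np.maximum(zc, self.barrel_length))
        else:
            rz = np.asarray(self.radius(np.maximum(zc, self.barrel_length)))
            v_cone = np.pi * lc / (3.0 * (rb - ro)) * (rz**3 - ro**3)
        v_barrel = np.pi * rb * rb * np.maximum(self.barrel_length - zc, 0.0)
        out = v_barrel + v_cone
        return out if out.ndim else float(out)

    def z_at_volume_from_outlet(self, volume: float) -> float:
        """Inverse of :meth:`volume_to_outlet` (volume measured from the outlet)."""
        total = self.volume_to_outlet(0.0)
        if not -1e-12 * total <= volume <= total * (1 + 1e-12):
            raise DomainError(f"volume {volume} outside [0, total fluid volume]")
        volume = min(max(volume, 0.0), total)
        rb, ro, lc = self.barrel_radius, self.outlet_radius, self.cone_length
        if volume <= self.cone_volume:
            if rb == ro:
                return self.total_length - volume / (np.pi * rb * rb)
            rz = (ro**3 + 3.0 * (rb - ro) * volume / (np.pi * lc)) ** (1.0 / 3.0)
            return self.barrel_length + lc * (rb - rz) / (rb - ro)
        return self.barrel_length - (volume - self.cone_volume) / (np.pi * rb * rb)


@dataclass(frozen=True)
class BlockFill:
    """Axial block lengths of the AB fill; block A sits on the outlet side."""

    block_a_length: float
    block_b_length: float

    def __post_init__(self) -> None:
        if self.block_a_length <= 0 or self.block_b_length <= 0:
            raise DomainError("block lengths must be > 0")

    @property
    def ratio(self) -> float:
        return self.block_a_length / self.block_b_length

    def validate_against(self, geom: CartridgeGeometry) -> None:
        total = self.block_a_length + self.block_b_length
        if total > geom.barrel_length * (1 + 1e-12):
            raise DomainError(
                f"fill length {total} exceeds barrel length {geom.barrel_length}")


@dataclass(frozen=True)
class ExtrusionSettings:
    """Piston drive, transient stepping, wall treatment and print kinematics."""

    piston_speed: float = 5e-3      # m/s
    time_step: float = 0.1          # s
    wall_mode: str = "slip"
    print_speed: float = 20e-3      # m/s

    def __post_init__(self) -> None:
        if self.piston_speed <= 0 or self.time_step <= 0 or self.print_speed <= 0:
            raise DomainError("piston_speed, time_step and print_speed must be > 0")
        if self.wall_mode not in WALL_MODES:
            raise DomainError(f"wall_mode must be one of {WALL_MODES}, got {self.wall_mode!r}")


def profile_shape(xi, n: float, wall_mode: str):
    """Dimensionless axial velocity multiplier phi(xi), xi = r/R in [0, 1].

    slip    : phi = 1 (plug).
    no_slip : phi = ((3n+1)/(n+1)) * (1 - xi**((n+1)/n)), the fully developed
              power-law tube profile.

    Both shapes satisfy ``2 * integral(phi * xi, xi=0..1) = 1`` so the
    cross-section mean of phi is exactly one.
    """
    if wall_mode not in WALL_MODES:
        raise DomainError(f"wall_mode must be one of {WALL_MODES}, got {wall_mode!r}")
    if n <= 0:
        raise DomainError(f"flow index must be > 0, got n={n}")
    x = np.asarray(xi, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise DomainError("xi must lie in [0, 1]")
    if wall_mode == "slip":
        out = np.ones_like(x)
    else:
        m = (n + 1.0) / n
        out = (3.0 * n + 1.0) / (n + 1.0) * (1.0 - x**m)
    return out if out.ndim else float(out)


def flux_fraction(xi, n: float, wall_mode: str):
    """Cumulative flux fraction Psi(xi) = 2 * integral(phi * s, s=0..xi).

    Psi(0) = 0, Psi(1) = 1; the closed forms are xi**2 for slip and
    a*(xi**2 - 2*xi**(m+2)/(m+2)) with a = (3n+1)/(n+1), m = (n+1)/n for no_slip.
    """
    if wall_mode not in WALL_MODES:
        raise DomainError(f"wall_mode must be one of {WALL_MODES}, got {wall_mode!r}")
    if n <= 0:
        raise DomainError(f"flow index must be > 0, got n={n}")
    x = np.asarray(xi, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise DomainError("xi must lie in [0, 1]")
    if wall_mode == "slip":
        out = x * x
    else:
        a = (3.0 * n + 1.0) / (n + 1.0)
        m = (n + 1.0) / n
        out = a * (x * x - 2.0 * x ** (m + 2.0) / (m + 2.0))
    return out if out.ndim else float(out)


def invert_flux_fraction(psi, n: float, wall_mode: str):
    """Solve Psi(xi) = psi for xi (vectorized, monotone bisection)."""
    p = np.atleast_1d(np.asarray(psi, dtype=float))
    if np.any(p < 0) or np.any(p > 1):
        raise DomainError("psi must lie in [0, 1]")
    if wall_mode == "slip":
        out = np.sqrt(p)
    else:
        lo = np.zeros_like(p)
        hi = np.ones_like(p)
        for _ in range(60):  # bisection: robust near the zero-derivative wall
            mid = 0.5 * (lo + hi)
            below = flux_fraction(mid, n, wall_mode) < p
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        out = 0.5 * (lo + hi)
    return out if np.ndim(psi) else float(out[0])


@dataclass(frozen=True)
class VelocityField:
    """Quasi-steady, mass-conserving velocity field in the cartridge.

    Steady in the lab frame while the piston travels the straight barrel; the
    piston position only bounds the fluid domain.
    """

    geometry: CartridgeGeometry
    settings: ExtrusionSettings
    params: PowerLawParams

    @property
    def flow_rate(self) -> float:
        """Total volumetric flow Q = v * pi * R_b**2 [m^3/s]."""
        return self.settings.piston_speed * np.pi * self.geometry.barrel_radius**2

    def mean_velocity(self, z):
        """Cross-section mean axial velocity U(z) = Q / (pi R(z)^2)."""
        r = np.asarray(self.geometry.radius(z))
        out = self.flow_rate / (np.pi * r * r)
        return out if out.ndim else float(out)

    def _velocity_unchecked(self, r, z):
        """(u_r, u_z) without domain checks; z is clamped into the geometry."""
        geom = self.geometry
        z = np.asarray(z, dtype=float)
        rad = np.asarray(geom.radius(z))
        xi = np.clip(np.asarray(r, dtype=float) / rad, 0.0, 1.0)
        phi = profile_shape(xi, self.params.n, self.settings.wall_mode)
        u_z = self.mean_velocity(z) * phi
        u_r = u_z * xi * np.asarray(geom.dradius_dz(z))
        return u_r, u_z

    def velocity(self, r, z, piston_z: float = 0.0):
        """(u_r, u_z) at (r, z) for a given piston position.

        Raises :class:`StateError` if the piston lies outside the barrel or
        the query point lies behind the piston / beyond the outlet, and
        :class:`DomainError` if r falls outside the local cross-section.
        """
        geom = self.geometry
        if not 0 <= piston_z <= geom.total_length:
            raise StateError(f"piston position {piston_z} outside [0, {geom.total_length}]")
        z_arr = np.asarray(z, dtype=float)
        if np.any(z_arr < piston_z - 1e-12) or np.any(z_arr > geom.total_length + 1e-12):
            raise StateError("query point outside the fluid domain")
        r_arr = np.asarray(r, dtype=float)
        rad = np.asarray(geom.radius(z_arr))
        if np.any(r_arr < 0) or np.any(r_arr > rad * (1 + 1e-9)):
            raise DomainError("radial position outside the local cross-section")
        u_r, u_z = self._velocity_unchecked(r_arr, z_arr)
        if np.ndim(r) == 0 and np.ndim(z) == 0:
            return float(u_r), float(u_z)
        return u_r, u_z

    def cross_section_flux(self, z) -> float:
        """Volume flux 2*pi*integral(u_z * r dr) through the section at z (quadrature)."""
        from scipy.integrate import quad

        rad = float(np.asarray(self.geometry.radius(z)))

        def integrand(r):
            return self._velocity_unchecked(r, z)[1] * r

        val, _ = quad(integrand, 0.0, rad, limit=200)
        return 2.0 * np.pi * val


def build_velocity_field(geom: CartridgeGeometry, settings: ExtrusionSettings,
                         params: PowerLawParams) -> VelocityField:
    """Construct the quasi-steady field for a validated geometry/settings pair."""
    return VelocityField(geometry=geom, settings=settings, params=params)


@dataclass(frozen=True)
class Streamline:
    """An integrated particle path ending at the outlet plane."""

    r: np.ndarray
    z: np.ndarray
    t: np.ndarray
    transit_time: float


def streamline(field: VelocityField, start: tuple[float, float],
               step: float | None = None, max_time: float | None = None) -> Streamline:
    """Trace a path from ``start = (r0, z0)`` to the outlet by RK4 integration.

    The step size adapts to the local velocity so the axial advance per step
    stays small relative to the remaining distance (refined inside the
    contraction); the final partial step is linearly interpolated onto the
    outlet plane.  A path that fails to exit within ``max_time`` (default:
    500 plug transits of the full cartridge) raises ConvergenceError.
    """
    geom = field.geometry
    r0, z0 = float(start[0]), float(start[1])
    rad0 = float(np.asarray(geom.radius(z0)))
    if not (0 <= z0 < geom.total_length) or not (0 <= r0 <= rad0):
        raise DomainError(f"start point ({r0}, {z0}) outside the fluid domain")
    if max_time is None:
        max_time = 500.0 * geom.volume_to_outlet(0.0) / field.flow_rate

    l_out = geom.total_length
    h_cap = geom.total_length / 200.0
    h_floor = geom.outlet_radius / 10.0
    rs, zs, ts = [r0], [z0], [0.0]
    r, z, t = r0, z0, 0.0
    for _ in range(2_000_000):
        _, u_z = field._velocity_unchecked(r, z)
        if u_z <= 0:
            raise ConvergenceError("stagnant streamline: zero axial velocity")
        h_z = max(min(h_cap, 0.1 * (l_out - z)), h_floor)
        if z < geom.barrel_length - 1e-15:
            # land on the barrel/cone kink rather than stepping across it
            h_z = min(h_z, geom.barrel_length - z)
        # likewise land on the outlet plane so stages never straddle its kink
        h_z = min(h_z, l_out - z)
        dt = h_z / u_z

        def rhs(rr, zz):
            return field._velocity_unchecked(rr, min(zz, l_out))

        k1r, k1z = rhs(r, z)
        k2r, k2z = rhs(r + 0.5 * dt * k1r, z + 0.5 * dt * k1z)
        k3r, k3z = rhs(r + 0.5 * dt * k2r, z + 0.5 * dt * k2z)
        k4r, k4z = rhs(r + dt * k3r, z + dt * k3z)
        r_new = r + dt / 6.0 * (k1r + 2 * k2r + 2 * k3r + k4r)
        z_new = z + dt / 6.0 * (k1z + 2 * k2z + 2 * k3z + k4z)
        if z_new >= l_out:
            frac = (l_out - z) / (z_new - z)
            t += frac * dt
            r += frac * (r_new - r)
            z = l_out
            rs.append(r), zs.append(z), ts.append(t)
            return Streamline(np.array(rs), np.array(zs), np.array(ts), transit_time=t)
        if abs(z_new - geom.barrel_length) < 1e-15:
            # nudge off the kink so the next step's stages all see cone slope
            z_new = np.nextafter(geom.barrel_length, l_out)
        r, z, t = max(r_new, 0.0), z_new, t + dt
        rs.append(r), zs.append(z), ts.append(t)
        if t > max_time:
            break
    raise ConvergenceError(
        f"streamline from ({r0}, {z0}) did not reach the outlet within {max_time} s")
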