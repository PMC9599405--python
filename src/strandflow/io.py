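"""Readers and writers for the package's plain-text interfaces.

Flow curves are CSV with mandatory header and ``#`` comment lines; columns
``shear_rate_per_s`` plus either ``shear_stress_Pa`` or ``viscosity_Pa_s``
(viscosity is converted to stress on read, tau = eta * gdot, so the fitter
always sees stress).  Run configuration is YAML with millimetre-denominated
geometry keys.  Simulation products are written as CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError
from .flowfield import BlockFill, CartridgeGeometry, ExtrusionSettings
from .rheology import FlowCurve, PowerLawParams
from .simulate import CrossSection, OutletSeries, StrandProfile

__all__ = [
    "read_flow_curve",
    "write_flow_curve",
    "write_power_law_params",
    "read_power_law_params",
    "load_run_config",
    "write_outlet_series",
    "read_outlet_series",
    "write_strand_profile",
    "read_strand_profile",
    "write_snapshots",
    "write_metrics",
    "write_manifest",
]


def read_flow_curve(path) -> FlowCurve:
    df = pd.read_csv(path, comment="#")
    if "shear_rate_per_s" not in df.columns:
        raise DomainError(f"{path}: missing required column 'shear_rate_per_s'")
    gdot = df["shear_rate_per_s"].to_numpy(dtype=float)
    if "shear_stress_Pa" in df.columns:
        tau = df["shear_stress_Pa"].to_numpy(dtype=float)
    elif "viscosity_Pa_s" in df.columns:
        tau = df["viscosity_Pa_s"].to_numpy(dtype=float) * gdot
    else:
        raise DomainError(
            f"{path}: need a 'shear_stress_Pa' or 'viscosity_Pa_s' column")
    return FlowCurve(shear_rate=gdot, shear_stress=tau)


def write_flow_curve(curve: FlowCurve, path) -> None:
    pd.DataFrame({"shear_rate_per_s": curve.shear_rate,
                  "shear_stress_Pa": curve.shear_stress}).to_csv(path, index=False)


def write_power_law_params(params: PowerLawParams, n_points_used: int, path) -> None:
    Path(path).write_text(json.dumps({
        "k_Pa_sn": params.k, "n": params.n,
        "fit_range_per_s": list(params.fit_range),
        "n_points_used": int(n_points_used)}, indent=2) + "\n")


def read_power_law_params(path) -> PowerLawParams:
    d = json.loads(Path(path).read_text())
    return PowerLawParams(k=d["k_Pa_sn"], n=d["n"], fit_range=tuple(d["fit_range_per_s"]))


def load_run_config(path) -> dict:
    """Parse a YAML run config into model objects.

    Returns a dict with ``geometry``, ``fill``, ``settings`` and (when the
    rheology block is present) ``params``.  Geometry accepts either
    ``outlet_radius_mm`` or a ``needle_gauge`` preset.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise DomainError(f"{path}: config must be a mapping")

    def mm(key, default=None):
        val = raw.get(key, default)
        if val is None:
            raise DomainError(f"{path}: missing required key '{key}'")
        return float(val) * 1e-3

    if "needle_gauge" in raw:
        geom = CartridgeGeometry.from_gauge(
            int(raw["needle_gauge"]),
            barrel_radius=mm("barrel_radius_mm", 4.8),
            barrel_length=mm("barrel_length_mm", 55.0),
            cone_length=mm("cone_length_mm", 8.0))
    else:
        geom = CartridgeGeometry(
            barrel_radius=mm("barrel_radius_mm", 4.8),
            barrel_length=mm("barrel_length_mm", 55.0),
            cone_length=mm("cone_length_mm", 8.0),
            outlet_radius=mm("outlet_radius_mm"))
    fill = BlockFill(block_a_length=mm("block_A_mm"), block_b_length=mm("block_B_mm"))
    settings = ExtrusionSettings(
        piston_speed=mm("piston_speed_mm_s", 5.0),
        time_step=float(raw.get("time_step_s", 0.1)),
        wall_mode=str(raw.get("wall_mode", "slip")),
        print_speed=mm("print_speed_mm_s", 20.0))
    out = {"geometry": geom, "fill": fill, "settings": settings, "raw": raw}
    if "rheology_k_Pa_sn" in raw or "rheology_n" in raw:
        out["params"] = PowerLawParams(
            k=float(raw["rheology_k_Pa_sn"]), n=float(raw["rheology_n"]),
            fit_range=tuple(raw.get("rheology_fit_range_per_s", (0.1, 10.0))))
    return out


def write_outlet_series(series: OutletSeries, path) -> None:
    series.to_dataframe().to_csv(path, index=False)


def read_outlet_series(path) -> OutletSeries:
    df = pd.read_csv(path, comment="#")
    times = df["time_s"].to_numpy(dtype=float)
    dts = np.diff(times)
    dts = np.append(dts, dts[-1] if dts.size else 1.0)
    return OutletSeries(times=times, dts=dts, Q=df["Q_m3_s"].to_numpy(dtype=float),
                        C_A=df["C_A"].to_numpy(dtype=float),
                        C_B=df["C_B"].to_numpy(dtype=float))


def write_strand_profile(profile: StrandProfile, path) -> None:
    pd.DataFrame({"s_m": profile.positions, "C_A": profile.values}).to_csv(path, index=False)


def read_strand_profile(path) -> StrandProfile:
    df = pd.read_csv(path, comment="#")
    cols = [c for c in df.columns if c != "s_m"]
    if "s_m" not in df.columns or not cols:
        raise DomainError(f"{path}: need columns 's_m' and a value column")
    return StrandProfile(positions=df["s_m"].to_numpy(dtype=float),
                         values=df[cols[0]].to_numpy(dtype=float))


def write_snapshots(snapshots: list[CrossSection], path) -> None:
    rows = []
    for xs in snapshots:
        for i, c in enumerate(xs.C_A):
            rows.append((xs.time, xs.r_edges[i], xs.r_edges[i + 1], c))
    pd.DataFrame(rows, columns=["time_s", "r_inner_m", "r_outer_m", "C_A"]).to_csv(
        path, index=False)


def write_metrics(metrics, path) -> None:
    Path(path).write_text(json.dumps(metrics.to_dict(), indent=2) + "\n")


def write_manifest(config: dict, path) -> None:
    from . import __version__

    def jsonable(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "__dataclass_fields__"):
            return {k: jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
        if isinstance(obj, dict):
            return {k: jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [jsonable(v) for v in obj]
        return obj

    Path(path).write_text(json.dumps(
        {"code_version": __version__, **jsonable(config)}, indent=2, default=str) + "\n")
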