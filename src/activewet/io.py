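"""File I/O: profiles and traces as CSV, fields and maps as CSV + JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fields import RadialProfile, VectorField
from .kinetics import KineticTrace
from .tfm import TractionMap


def write_profile(profile: RadialProfile, path) -> None:
    """Radial profile as CSV with columns r_um, value, sem, n."""
    pd.DataFrame({
        "r_um": profile.r_centers, "value": profile.value,
        "sem": profile.sem, "n": profile.n,
    }).to_csv(path, index=False)


def read_profile(path, units: str = "um/h", label: str = "") -> RadialProfile:
    df = pd.read_csv(path)
    r = df["r_um"].to_numpy(dtype=float)
    bw = float(np.min(np.diff(r))) if r.size > 1 else 1.0
    return RadialProfile(
        r_centers=r, value=df["value"].to_numpy(dtype=float),
        sem=df["sem"].to_numpy(dtype=float), n=df["n"].to_numpy(dtype=int),
        bin_width=bw, units=units, label=label,
    )


def write_field(field: VectorField, path, sidecar: dict | None = None) -> None:
    """Vector field as CSV (x_um, y_um, u, v, valid) + JSON sidecar."""
    X, Y = field.xy()
    pd.DataFrame({
        "x_um": X.ravel(), "y_um": Y.ravel(),
        "u_umph": field.u.ravel(), "v_umph": field.v.ravel(),
        "valid": field.mask.ravel().astype(int),
    }).to_csv(path, index=False)
    meta = {
        "pixel_size_um": field.pixel_size, "dt_h": field.dt, "t_h": field.t,
        "units": field.units, "nx": int(field.grid_x.size),
        "ny": int(field.grid_y.size),
    }
    if sidecar:
        meta.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_field(path) -> VectorField:
    df = pd.read_csv(path)
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    gx = np.unique(df["x_um"].to_numpy(dtype=float))
    gy = np.unique(df["y_um"].to_numpy(dtype=float))
    shape = (gy.size, gx.size)
    if len(df) != shape[0] * shape[1]:
        raise ValueError(f"{path}: not a full regular grid")
    order = np.lexsort((df["x_um"], df["y_um"]))
    u = df["u_umph"].to_numpy(dtype=float)[order].reshape(shape)
    v = df["v_umph"].to_numpy(dtype=float)[order].reshape(shape)
    mask = df["valid"].to_numpy()[order].reshape(shape).astype(bool)
    return VectorField(
        grid_x=gx, grid_y=gy, u=u, v=v, mask=mask,
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        dt=meta.get("dt_h"), t=float(meta.get("t_h", 0.0)),
        units=meta.get("units", "um/h"),
    )


def write_traction_map(tmap: TractionMap, path, meta: dict | None = None) -> None:
    X, Y = np.meshgrid(tmap.grid_x, tmap.grid_y)
    pd.DataFrame({
        "x_um": X.ravel(), "y_um": Y.ravel(),
        "tx_pa": tmap.tx.ravel(), "ty_pa": tmap.ty.ravel(),
    }).to_csv(path, index=False)
    sidecar = {"lambda": None if np.isnan(tmap.lam) else tmap.lam}
    if meta:
        sidecar.update(meta)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_displacements(path) -> pd.DataFrame:
    """Bead displacement table: columns x_um, y_um, ux_um, uy_um."""
    df = pd.read_csv(path)
    required = {"x_um", "y_um", "ux_um", "uy_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df[["x_um", "y_um", "ux_um", "uy_um"]]


def write_trace(trace: KineticTrace, path) -> None:
    pd.DataFrame({
        f"t_{trace.t_units}": trace.t,
        f"y_{trace.y_units or 'value'}": trace.y,
    }).to_csv(path, index=False)


def read_trace(path, label: str = "") -> KineticTrace:
    df = pd.read_csv(path)
    tcol = df.columns[0]
    ycol = df.columns[1]
    t_units = tcol.split("_", 1)[1] if "_" in tcol else "h"
    y_units = ycol.split("_", 1)[1] if "_" in ycol else ""
    return KineticTrace(
        t=df[tcol].to_numpy(dtype=float), y=df[ycol].to_numpy(dtype=float),
        t_units=t_units, y_units="" if y_units == "value" else y_units,
        label=label,
    )
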