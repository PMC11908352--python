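"""Seeded synthetic-data generators with machine-readable ground truth.

Each generator emulates one class of input the analysis chain consumes:

- radial velocity fields drawn from the annular polar-fluid solution on
  a growing/melting annulus, plus additive Gaussian noise;
- Gaussian-speckle image pairs displaced by a known field (PIV fixture);
- bead displacement tables from an axisymmetric Bessel traction profile
  pushed through the Boussinesq forward operator (TFM fixture);
- exponential fusion / recoil / linear area / melting traces;
- growing-disk segmentation masks.

All randomness flows from one explicit seed per call; every generator
returns a truth record describing exactly what it produced, so each
downstream estimator has a recovery test keyed to it.

Default noise levels: 5% of the peak velocity for velocity fields,
0.05 um positional noise for beads, 3% for kinetic traces — small enough
for recovery, large enough that uncertainty estimates are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd

from .fields import VectorField
from .model import traction_profile, velocity_profile
from .params import ModelParams, TractionFitParams
from .tfm import ElasticSubstrate, TractionMap, forward_displacement

__all__ = [
    "SpreadScenario",
    "GridSpec",
    "gen_velocity_fields",
    "gen_speckle_pair",
    "gen_bead_displacements",
    "gen_kinetic_traces",
    "gen_disk_masks",
    "gen_correlated_field",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular PIV-like grid: (ny, nx) nodes spaced ``spacing`` um apart."""

    shape: tuple[int, int] = (48, 48)
    spacing: float = 10.0

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.shape
        return np.arange(nx) * self.spacing, np.arange(ny) * self.spacing

    def center(self) -> tuple[float, float]:
        ny, nx = self.shape
        return ((nx - 1) / 2.0 * self.spacing, (ny - 1) / 2.0 * self.spacing)


@dataclass(frozen=True)
class SpreadScenario:
    """A spreading spheroid: growing front, melting core, noisy flow.

    ``R(t) = R + R_growth t`` and ``R1(t) = R1 + R1_melt t`` (melting
    means ``R1_melt <= 0``); parameters must stay valid over all frames.
    """

    params0: ModelParams
    R_growth: float = 5.0
    R1_melt: float = -2.0
    noise_sd: float = 0.05
    n_frames: int = 10
    dt: float = 1.0 / 6.0
    seed: int = 0

    def params_at(self, t: float) -> ModelParams:
        p = self.params0
        return ModelParams(A=p.A, B=p.B, Lc=p.Lc,
                           R=p.R + self.R_growth * t,
                           R1=max(p.R1 + self.R1_melt * t, 0.0))

    def validate(self) -> None:
        for k in range(self.n_frames):
            self.params_at(k * self.dt)  # raises if invalid


def gen_velocity_fields(scn: SpreadScenario, grid: GridSpec = GridSpec()
                        ) -> tuple[list[VectorField], dict[str, Any]]:
    """Model-driven radial velocity fields on a regular grid.

    At each frame the closed-form radial velocity is projected on the
    grid (``v = v_r(r) u_r``), isotropic Gaussian noise of standard
    deviation ``noise_sd * max |v|`` is added, and nodes outside the
    annulus [R1, R] are masked.

    Returns
    -------
    (fields, truth)
        ``truth`` records the scenario, grid, center, and per-frame
        parameters.
    """
    scn.validate()
    rng = np.random.default_rng(scn.seed)
    gx, gy = grid.coords()
    cx, cy = grid.center()
    X, Y = np.meshgrid(gx, gy)
    dx, dy = X - cx, Y - cy
    r = np.hypot(dx, dy)

    fields: list[VectorField] = []
    frames: list[dict[str, float]] = []
    for k in range(scn.n_frames):
        t = k * scn.dt
        p = scn.params_at(t)
        inside = (r >= p.R1) & (r <= p.R) & (r > 0)
        vr = np.zeros_like(r)
        vr[inside] = velocity_profile(r[inside], p)
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(inside, vr * dx / np.where(r > 0, r, 1.0), 0.0)
            uy = np.where(inside, vr * dy / np.where(r > 0, r, 1.0), 0.0)
        vmax = np.abs(vr).max()
        if scn.noise_sd > 0 and vmax > 0:
            ux = ux + rng.normal(0.0, scn.noise_sd * vmax, ux.shape)
            uy = uy + rng.normal(0.0, scn.noise_sd * vmax, uy.shape)
        fields.append(VectorField(
            grid_x=gx, grid_y=gy, u=np.where(inside, ux, 0.0),
            v=np.where(inside, uy, 0.0), mask=inside,
            pixel_size=grid.spacing, dt=scn.dt, t=t,
        ))
        frames.append({"t": t, "A": p.A, "B": p.B, "Lc": p.Lc,
                       "R": p.R, "R1": p.R1})
    truth = {
        "kind": "velocity_fields",
        "center_um": [cx, cy],
        "grid": {"shape": list(grid.shape), "spacing_um": grid.spacing},
        "noise_sd": scn.noise_sd,
        "seed": scn.seed,
        "frames": frames,
    }
    return fields, truth


def _render_spots(shape: tuple[int, int], xs: np.ndarray, ys: np.ndarray,
                  amps: np.ndarray, sigma: float) -> np.ndarray:
    """Sum of Gaussian spots at continuous positions (no pixel rounding)."""
    img = np.zeros(shape)
    half = int(np.ceil(4 * sigma))
    h, w = shape
    for x, y, a in zip(xs, ys, amps):
        x0, y0 = int(np.floor(x)), int(np.floor(y))
        xlo, xhi = max(0, x0 - half), min(w, x0 + half + 1)
        ylo, yhi = max(0, y0 - half), min(h, y0 + half + 1)
        if xlo >= xhi or ylo >= yhi:
            continue
        px = np.arange(xlo, xhi)
        py = np.arange(ylo, yhi)
        gx = np.exp(-((px - x) ** 2) / (2 * sigma**2))
        gy = np.exp(-((py - y) ** 2) / (2 * sigma**2))
        img[ylo:yhi, xlo:xhi] += a * np.outer(gy, gx)
    return img


def gen_speckle_pair(shape: tuple[int, int] = (256, 256),
                     density: float = 0.02,
                     displacement: tuple[float, float] | Callable = (0.0, 0.0),
                     seed: int = 0, spot_sigma: float = 1.5,
                     window: int | None = None
                     ) -> tuple[np.ndarray, np.ndarray, dict[str, Any]]:
    """Speckle image pair with a known imposed displacement, px.

    Spots are Poisson-scattered Gaussians (sigma ~ 1.5 px); the second
    image renders each spot at its displaced continuous position (either
    a constant ``(dx, dy)`` or a callable ``(x, y) -> (dx, dy)``).

    Returns (img_a, img_b, truth); ``truth['low_density']`` warns when
    fewer than ~10 spots fall in a ``window``-sized interrogation area.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    n = rng.poisson(density * h * w)
    xs = rng.uniform(0, w, n)
    ys = rng.uniform(0, h, n)
    amps = rng.uniform(0.5, 1.0, n)
    img_a = _render_spots(shape, xs, ys, amps, spot_sigma)
    if callable(displacement):
        d = np.array([displacement(x, y) for x, y in zip(xs, ys)], dtype=float)
        dxs, dys = d[:, 0], d[:, 1]
    else:
        dxs = np.full(n, float(displacement[0]))
        dys = np.full(n, float(displacement[1]))
    img_b = _render_spots(shape, xs + dxs, ys + dys, amps, spot_sigma)
    low = window is not None and density * window**2 < 10
    truth = {"kind": "speckle_pair", "n_spots": int(n), "seed": seed,
             "spot_sigma": spot_sigma, "low_density": bool(low),
             "displacement": "callable" if callable(displacement)
             else [float(displacement[0]), float(displacement[1])]}
    return img_a, img_b, truth


def gen_bead_displacements(traction: TractionFitParams,
                           substrate: ElasticSubstrate = ElasticSubstrate(),
                           n_beads: int = 200_000, noise_um: float = 0.05,
                           seed: int = 0, grid_n: int = 256,
                           extent: float | None = None
                           ) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Scattered bead displacements for an axisymmetric Bessel traction.

    The inward radial traction ``Tr(r) = -T0 I1(r/Lc)/I1(R/Lc)`` is
    rasterized on a ``grid_n`` x ``grid_n`` periodic grid, pushed through
    the Boussinesq forward operator, and sampled (bilinearly) at uniform
    random bead positions with Gaussian positional noise.

    Defaults emulate a densely functionalized substrate (~1 bead/um^2
    over a 2.25 R field of view), which resolves the traction step at the
    monolayer edge; sparser tables blur the edge and bias T0 low.

    Returns (table, truth) with table columns x_um, y_um, ux_um, uy_um.
    """
    rng = np.random.default_rng(seed)
    if extent is None:
        extent = 2.25 * traction.R
    spacing = extent / grid_n
    g = np.arange(grid_n) * spacing
    c = (grid_n - 1) / 2.0 * spacing
    X, Y = np.meshgrid(g, g)
    dx, dy = X - c, Y - c
    r = np.hypot(dx, dy)
    tr = np.zeros_like(r)
    inside = (r > 0) & (r <= traction.R)
    tr[inside] = traction_profile(r[inside], traction)
    tx = np.where(inside, tr * dx / np.where(r > 0, r, 1.0), 0.0)
    ty = np.where(inside, tr * dy / np.where(r > 0, r, 1.0), 0.0)
    tmap = TractionMap(grid_x=g, grid_y=g, tx=tx, ty=ty)
    disp = forward_displacement(tmap, substrate)

    from scipy.interpolate import RegularGridInterpolator

    fu = RegularGridInterpolator((g, g), disp.u)   # (y, x) ordering
    fv = RegularGridInterpolator((g, g), disp.v)
    bx = rng.uniform(g[0], g[-1], n_beads)
    by = rng.uniform(g[0], g[-1], n_beads)
    pts = np.column_stack([by, bx])
    ux = fu(pts)
    uy = fv(pts)
    if noise_um > 0:
        ux = ux + rng.normal(0.0, noise_um, n_beads)
        uy = uy + rng.normal(0.0, noise_um, n_beads)
    table = pd.DataFrame({"x_um": bx, "y_um": by, "ux_um": ux, "uy_um": uy})
    truth = {
        "kind": "bead_displacements",
        "T0": traction.T0, "Lc": traction.Lc, "R": traction.R,
        "E_kPa": substrate.E, "nu": substrate.nu,
        "center_um": [c, c], "spacing_um": spacing, "grid_n": grid_n,
        "n_beads": n_beads, "noise_um": noise_um, "seed": seed,
    }
    return table, truth


_FUSION_TIMES = np.array([1.0, 8.0, 24.0, 48.0, 72.0])  # imaging times, h


def gen_kinetic_traces(kind: str, truth_params: dict[str, float],
                       noise: float = 0.03,
                       times: np.ndarray | None = None, seed: int = 0):
    """Exact kinetic model curve plus Gaussian noise at stated times.

    Parameters
    ----------
    kind : {'fusion', 'recoil', 'area', 'melting'}
        fusion:  y = amplitude (1 - exp(-gamma t)), default times the
                 coalescence imaging grid (1, 8, 24, 48, 72 h);
        recoil:  y = (initial_recoil / k)(1 - exp(-k t)), times in s;
        area:    y = intercept + slope t (um^2);
        melting: y = intercept + rate t (R1/R0, dimensionless).
    truth_params : dict
        Model parameters, keys as above.
    noise : float
        Gaussian noise sd as a fraction of the curve's final magnitude
        (absolute when the curve is flat).
    times : ndarray, optional
    seed : int

    Returns
    -------
    (KineticTrace, truth_record)
    """
    from .kinetics import KineticTrace

    rng = np.random.default_rng(seed)
    p = dict(truth_params)
    if kind == "fusion":
        t = _FUSION_TIMES if times is None else np.asarray(times, dtype=float)
        y = p["amplitude"] * (1.0 - np.exp(-p["gamma"] * t))
        units = ("h", "")
    elif kind == "recoil":
        t = np.linspace(0.0, 20.0, 21) if times is None else np.asarray(times, dtype=float)
        y = (p["initial_recoil"] / p["k"]) * (1.0 - np.exp(-p["k"] * t))
        units = ("s", "um")
    elif kind == "area":
        t = np.linspace(0.0, 24.0, 49) if times is None else np.asarray(times, dtype=float)
        y = p["intercept"] + p["slope"] * t
        units = ("h", "um^2")
    elif kind == "melting":
        t = np.linspace(0.0, 24.0, 25) if times is None else np.asarray(times, dtype=float)
        y = p["intercept"] + p["rate"] * t
        units = ("h", "")
    else:
        raise ValueError(f"unknown trace kind {kind!r}")
    scale = max(abs(y[-1]), abs(y).max())
    sd = noise * scale if scale > 0 else noise
    if noise > 0:
        y = y + rng.normal(0.0, sd, y.shape)
    trace = KineticTrace(t=t, y=y, t_units=units[0], y_units=units[1], label=kind)
    truth = {"kind": kind, "params": p, "noise_sd": sd, "seed": seed,
             "times": t.tolist()}
    return trace, truth


def gen_disk_masks(shape: tuple[int, int], center_px: tuple[float, float],
                   radii_px: Sequence[float]) -> list[np.ndarray]:
    """Growing-disk boolean masks emulating contact-area segmentation."""
    h, w = shape
    Y, X = np.indices(shape)
    cx, cy = center_px
    r = np.hypot(X - cx, Y - cy)
    return [r <= rad for rad in radii_px]


def segment_contact_area(img: np.ndarray, closing_radius: int = 2) -> np.ndarray:
    """Threshold + morphology segmentation for synthetic spheroid images.

    Otsu threshold, morphological closing, and largest connected
    component.  Intended only for the clean synthetic images produced in
    this module; phase-contrast segmentation of real movies needs a
    dedicated pipeline and masks are otherwise inputs.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label
    from skimage.morphology import closing, disk

    img = np.asarray(img, dtype=float)
    mask = img > threshold_otsu(img)
    mask = closing(mask, disk(closing_radius))
    labels = label(mask)
    if labels.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return labels == largest


def gen_correlated_field(shape: tuple[int, int], spacing: float, L0: float,
                         seed: int = 0, dt: float = 1.0) -> VectorField:
    """Gaussian random vector field with exponential spatial correlation.

    Each component is synthesized spectrally with the 2D power spectrum
    of an exponential correlation of length ``L0``,
    ``S(q) ~ (1 + (q L0)^2)^(-3/2)``, so the isotropic autocorrelation of
    the result decays as ``exp(-r/L0)``.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    qx = 2 * np.pi * np.fft.fftfreq(nx, d=spacing)[None, :]
    qy = 2 * np.pi * np.fft.fftfreq(ny, d=spacing)[:, None]
    q2 = qx**2 + qy**2
    amp = (1.0 + q2 * L0**2) ** (-0.75)
    comps = []
    for _ in range(2):
        white = rng.normal(size=shape)
        f = np.fft.fft2(white) * amp
        comp = np.fft.ifft2(f).real
        comps.append(comp / comp.std())
    gx = np.arange(nx) * spacing
    gy = np.arange(ny) * spacing
    return VectorField(grid_x=gx, grid_y=gy, u=comps[0], v=comps[1],
                       mask=np.ones(shape, dtype=bool), pixel_size=spacing,
                       dt=dt)
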