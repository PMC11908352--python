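"""Gridded 2D vector fields and their scalar summaries.

This module turns velocimetry / traction grids into the quantities the
analysis chain consumes: azimuthally averaged radial profiles, the
center-of-mass velocity, the RMS velocity fluctuation, per-node
alignment with the mean flow, and the velocity correlation length.

Conventions: coordinates are pixel centers, 0-based, origin at the
top-left pixel, x rightward, y downward; all lengths in um, times in h.
Masked-out nodes are excluded from every average (no zero filling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .results import FitResult, stderr_from_jacobian

__all__ = [
    "VectorField",
    "RadialProfile",
    "OrderParameters",
    "centroid",
    "radial_profile",
    "smooth_profiles",
    "rolling_smooth",
    "order_parameters",
    "correlation_length",
]


@dataclass
class VectorField:
    """A masked, grid-sampled 2D vector field.

    Attributes
    ----------
    grid_x, grid_y : ndarray
        1D window-center coordinates, um, strictly increasing.
    u, v : ndarray
        Components on the (ny, nx) grid; x- and y-components respectively.
    mask : ndarray of bool
        True where the node carries a valid vector.
    pixel_size : float
        um per pixel of the source images.
    dt : float or None
        Frame interval in h (None for static fields such as displacements).
    t : float
        Acquisition time, h.
    units : str
        Units of (u, v); "um/h" for velocities, "um" for displacements.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    mask: np.ndarray
    pixel_size: float = 1.0
    dt: float | None = None
    t: float = 0.0
    units: str = "um/h"

    def __post_init__(self) -> None:
        self.grid_x = np.asarray(self.grid_x, dtype=float)
        self.grid_y = np.asarray(self.grid_y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        shape = (self.grid_y.size, self.grid_x.size)
        if self.u.shape != shape or self.v.shape != shape or self.mask.shape != shape:
            raise ValueError("u, v, mask must have shape (len(grid_y), len(grid_x))")
        for g in (self.grid_x, self.grid_y):
            if g.size > 1 and np.any(np.diff(g) <= 0):
                raise ValueError("grid coordinates must be strictly increasing")
        if not np.all(np.isfinite(self.u[self.mask])) or not np.all(
            np.isfinite(self.v[self.mask])
        ):
            raise ValueError("u, v must be finite wherever mask is true")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid node coordinates (X, Y), each (ny, nx)."""
        return np.meshgrid(self.grid_x, self.grid_y)

    def filled(self, fill: float = 0.0) -> "VectorField":
        """Copy with invalid nodes replaced by ``fill`` and a full mask.

        FTTC needs a complete grid; zero-filling outside the convex hull
        of the tracked beads is the conventional choice.
        """
        u = np.where(self.mask, self.u, fill)
        v = np.where(self.mask, self.v, fill)
        return VectorField(
            grid_x=self.grid_x, grid_y=self.grid_y, u=u, v=v,
            mask=np.ones_like(self.mask), pixel_size=self.pixel_size,
            dt=self.dt, t=self.t, units=self.units,
        )

    def plot(self, ax=None, **quiver_kw):
        """Quiver plot of the valid vectors."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        X, Y = self.xy()
        m = self.mask
        ax.quiver(X[m], Y[m], self.u[m], -self.v[m], **quiver_kw)
        ax.set_xlabel("x (um)")
        ax.set_ylabel("y (um)")
        ax.invert_yaxis()
        ax.set_aspect("equal")
        return ax


@dataclass
class RadialProfile:
    """Azimuthally averaged radial component vs distance from a center.

    Attributes
    ----------
    r_centers : ndarray
        Bin-center radii, um, increasing; empty bins are omitted.
    value : ndarray
        Mean radial component per bin (field units).
    sem : ndarray
        Standard error of the mean per bin (0 for single-sample bins).
    n : ndarray
        Samples per bin (>= 1).
    bin_width : float
        Uniform bin width, um.
    units : str
    label : str
    short_window : bool
        Set by :func:`smooth_profiles` when fewer frames than the nominal
        smoothing window were available.
    """

    r_centers: np.ndarray
    value: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    bin_width: float
    units: str = "um/h"
    label: str = ""
    short_window: bool = False

    def __post_init__(self) -> None:
        self.r_centers = np.asarray(self.r_centers, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        k = self.r_centers.size
        if not (self.value.size == self.sem.size == self.n.size == k):
            raise ValueError("r_centers, value, sem, n must have equal length")
        if k > 1 and np.any(np.diff(self.r_centers) <= 0):
            raise ValueError("r_centers must be strictly increasing")
        if np.any(self.n < 1):
            raise ValueError("reported bins must contain at least one sample")

    def __len__(self) -> int:
        return self.r_centers.size

    def plot(self, ax=None, **errorbar_kw):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.r_centers, self.value, yerr=self.sem, fmt="o-", **errorbar_kw)
        ax.set_xlabel("r (um)")
        ax.set_ylabel(f"{self.label or 'radial component'} ({self.units})")
        return ax


@dataclass
class OrderParameters:
    """Collective-motion order parameters of one vector field.

    ``alignment`` is NaN where undefined (zero local speed, or a
    center-of-mass speed at machine-tolerance level); those nodes are
    excluded from ``mean_alignment``.
    """

    v_cm: np.ndarray
    v_rms: float
    alignment: np.ndarray

    @property
    def mean_alignment(self) -> float:
        a = self.alignment[np.isfinite(self.alignment)]
        return float(a.mean()) if a.size else float("nan")


def centroid(mask: np.ndarray, pixel_size: float = 1.0) -> tuple[float, float]:
    """Area centroid (x, y) of the true pixels, um, pixel-center convention.

    Pixel ``mask[i, j]`` has center ``(x, y) = (j, i) * pixel_size``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    iy, ix = np.nonzero(mask)
    return float(ix.mean() * pixel_size), float(iy.mean() * pixel_size)


def radial_profile(field: VectorField, center: tuple[float, float],
                   bin_width: float | None = None) -> RadialProfile:
    """Azimuthal average of the radial vector component about ``center``.

    At each valid node the radial component ``v_r = v . u_r`` is taken
    along the unit vector from ``center`` to the node, and nodes are
    binned by distance into uniform bins ``[k dr, (k+1) dr)``.  Nodes
    coinciding with the center (undefined direction) are skipped.

    Parameters
    ----------
    field : VectorField
    center : (float, float)
        (x, y) in um.
    bin_width : float, optional
        Bin width dr in um; defaults to one grid spacing.

    Returns
    -------
    RadialProfile
    """
    if bin_width is None:
        gx = field.grid_x
        bin_width = float(gx[1] - gx[0]) if gx.size > 1 else field.pixel_size
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if field.n_valid < 1:
        raise ValueError("field has no valid nodes")

    X, Y = field.xy()
    m = field.mask
    dx = X[m] - center[0]
    dy = Y[m] - center[1]
    r = np.hypot(dx, dy)
    ok = r > 0
    r, dx, dy = r[ok], dx[ok], dy[ok]
    vr = (field.u[m][ok] * dx + field.v[m][ok] * dy) / r

    idx = np.floor(r / bin_width).astype(int)
    order = np.argsort(idx, kind="stable")
    idx, vr, r = idx[order], vr[order], r[order]
    uniq, start = np.unique(idx, return_index=True)
    groups = np.split(vr, start[1:])

    centers, means, sems, counts = [], [], [], []
    for k, g in zip(uniq, groups):
        centers.append((k + 0.5) * bin_width)
        means.append(g.mean())
        sems.append(g.std(ddof=1) / np.sqrt(g.size) if g.size > 1 else 0.0)
        counts.append(g.size)
    return RadialProfile(
        r_centers=np.array(centers), value=np.array(means), sem=np.array(sems),
        n=np.array(counts), bin_width=bin_width, units=field.units,
    )


def smooth_profiles(profiles: Sequence[RadialProfile], window: int = 5) -> RadialProfile:
    """Per-bin mean of up to ``window`` consecutive radial profiles.

    Bins are matched by center (profiles must share bin width and
    alignment); a bin present in only some profiles is averaged over the
    profiles that report it, and ``n`` accumulates.  When fewer than
    ``window`` profiles are supplied the available ones are used and the
    result is flagged via ``short_window``.
    """
    if len(profiles) == 0:
        raise ValueError("no profiles to smooth")
    use = list(profiles[:window])
    bw = use[0].bin_width
    for p in use[1:]:
        if not np.isclose(p.bin_width, bw):
            raise ValueError("profiles do not share binning")

    acc: dict[int, list[tuple[float, float, int]]] = {}
    for p in use:
        keys = np.round(p.r_centers / bw - 0.5).astype(int)
        for k, val, sem, n in zip(keys, p.value, p.sem, p.n):
            acc.setdefault(int(k), []).append((val, sem, int(n)))
    keys = sorted(acc)
    centers, means, sems, counts = [], [], [], []
    for k in keys:
        vals = acc[k]
        m = len(vals)
        centers.append((k + 0.5) * bw)
        means.append(sum(v for v, _, _ in vals) / m)
        sems.append(np.sqrt(sum(s**2 for _, s, _ in vals)) / m)
        counts.append(sum(n for _, _, n in vals))
    return RadialProfile(
        r_centers=np.array(centers), value=np.array(means), sem=np.array(sems),
        n=np.array(counts), bin_width=bw, units=use[0].units,
        label=use[0].label, short_window=len(use) < window,
    )


def rolling_smooth(profiles: Sequence[RadialProfile], window: int = 5) -> list[RadialProfile]:
    """Rolling (trailing) window of :func:`smooth_profiles` over a sequence."""
    out = []
    for i in range(len(profiles)):
        lo = max(0, i - window + 1)
        out.append(smooth_profiles(profiles[lo : i + 1], window=window))
    return out


def order_parameters(field: VectorField, atol: float = 1e-12) -> OrderParameters:
    """Center-of-mass velocity, RMS fluctuation, and per-node alignment.

    v_CM is the mean vector over valid nodes; v_RMS is the root mean
    squared deviation from v_CM; the alignment ``a_i = cos(angle between
    v_i and v_CM)`` lies in [-1, 1] and is NaN where either speed is at
    tolerance level.
    """
    m = field.mask
    if not m.any():
        raise ValueError("field has no valid nodes")
    u, v = field.u[m], field.v[m]
    v_cm = np.array([u.mean(), v.mean()])
    dev2 = (u - v_cm[0]) ** 2 + (v - v_cm[1]) ** 2
    v_rms = float(np.sqrt(dev2.mean()))

    alignment = np.full(field.u.shape, np.nan)
    speed = np.hypot(u, v)
    cm_speed = float(np.hypot(*v_cm))
    scale = max(speed.max(), cm_speed, 1.0)
    defined = (speed > atol * scale) & (cm_speed > atol * scale)
    a = np.full(u.shape, np.nan)
    a[defined] = (u[defined] * v_cm[0] + v[defined] * v_cm[1]) / (
        speed[defined] * cm_speed
    )
    np.clip(a, -1.0, 1.0, out=a)
    alignment[m] = a
    return OrderParameters(v_cm=v_cm, v_rms=v_rms, alignment=alignment)


def _masked_autocorrelation(field: VectorField) -> tuple[np.ndarray, np.ndarray]:
    """Radially binned autocorrelation C(r) of the v_CM-subtracted velocity.

    Mask-aware: numerator and valid-pair counts are both computed by FFT
    with zero padding (no circular wrap); C(r) is the average dot product
    of fluctuation vectors over node pairs at lag r, azimuthally averaged
    into 1-grid-spacing bins and normalized so C(0) = 1.

    Returns (lags_um, C).
    """
    m = field.mask
    ops = order_parameters(field)
    du = np.where(m, field.u - ops.v_cm[0], 0.0)
    dv = np.where(m, field.v - ops.v_cm[1], 0.0)

    ny, nx = m.shape
    shape = (2 * ny, 2 * nx)
    fm = np.fft.rfft2(m.astype(float), shape)
    counts = np.fft.irfft2(fm * np.conj(fm), shape)
    num = np.zeros(shape)
    for comp in (du, dv):
        fc = np.fft.rfft2(comp, shape)
        num += np.fft.irfft2(fc * np.conj(fc), shape)
    num = np.fft.fftshift(num)
    counts = np.fft.fftshift(counts)

    spacing = float(field.grid_x[1] - field.grid_x[0]) if nx > 1 else field.pixel_size
    ky, kx = np.indices(shape)
    ky -= ny
    kx -= nx
    lag = np.hypot(kx, ky) * spacing

    valid = counts > 0.5
    bins = np.round(lag[valid] / spacing).astype(int)
    num_b = np.bincount(bins, weights=num[valid])
    cnt_b = np.bincount(bins, weights=counts[valid])
    keep = cnt_b > 0
    corr = num_b[keep] / cnt_b[keep]
    lags = np.arange(num_b.size)[keep] * spacing
    return lags, corr


def correlation_length(field: VectorField, max_lag: float) -> FitResult:
    """Velocity correlation length from an exponential fit exp(-r/Lcorr).

    The normalized spatial autocorrelation of the v_CM-subtracted velocity
    is computed by mask-aware FFT, azimuthally averaged, and fitted with
    ``exp(-r / Lcorr)`` over ``0 < r <= max_lag``.

    A spatially uniform field (no fluctuation energy) or a C(r) that
    never decays is flagged (``converged=False``).

    Returns
    -------
    FitResult
        Over the single parameter ``Lcorr`` (um); ``extra['lags']`` and
        ``extra['corr']`` carry the correlation curve.
    """
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")
    lags, corr = _masked_autocorrelation(field)
    c0 = corr[0]
    scale = max(np.hypot(field.u[field.mask], field.v[field.mask]).max(), 1.0)
    if c0 <= (1e-12 * scale) ** 2:
        # no fluctuations: C is 1 everywhere by convention, nothing decays
        ones = np.ones_like(corr)
        return FitResult(
            params={"Lcorr": float("nan")}, stderr={"Lcorr": float("nan")},
            window=(0.0, float(max_lag)), residual_rms=0.0, converged=False,
            n_points=int(lags.size), message="no velocity fluctuations: C(r) == 1",
            extra={"lags": lags, "corr": ones},
        )
    corr = corr / c0
    sel = (lags > 0) & (lags <= max_lag)
    if np.all(np.diff(corr[lags <= max_lag]) >= 0):
        return FitResult(
            params={"Lcorr": float("nan")}, stderr={"Lcorr": float("nan")},
            window=(0.0, float(max_lag)), residual_rms=float("nan"), converged=False,
            n_points=int(sel.sum()), message="correlation function does not decay",
            extra={"lags": lags, "corr": corr},
        )
    x, y = lags[sel], corr[sel]
    spacing = lags[1] - lags[0] if lags.size > 1 else 1.0

    def resid(theta):
        return np.exp(-x / theta[0]) - y

    # crude init: lag where C first drops below 1/e
    below = x[y < np.exp(-1.0)]
    l0 = float(below[0]) if below.size else float(x[-1] / 2)
    res = least_squares(resid, x0=[max(l0, 0.1 * spacing)],
                        bounds=([1e-6 * spacing], [np.inf]))
    se = stderr_from_jacobian(res.jac, res.fun)
    return FitResult(
        params={"Lcorr": float(res.x[0])}, stderr={"Lcorr": float(se[0])},
        window=(float(x[0]), float(x[-1])),
        residual_rms=float(np.sqrt(np.mean(res.fun**2))),
        converged=bool(res.success), n_points=int(x.size),
        extra={"lags": lags, "corr": corr},
    )
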