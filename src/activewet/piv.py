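"""Cross-correlation particle image velocimetry.

Displacements between consecutive frames are estimated per interrogation
window as the peak of the mean-subtracted (normalized) cross-correlation,
computed by FFT, restricted to +/- window/4, and refined to subpixel
accuracy by 3-point Gaussian peak interpolation.  Windows falling mostly
outside the analysis mask, or with zero intensity variance, are masked
out rather than raising.

No iterative window deformation is performed; an optional 3-sigma
local-median outlier filter replaces isolated spurious vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fields import VectorField

__all__ = ["PivConfig", "piv_pair", "piv_movie", "median_filter_outliers"]


@dataclass(frozen=True)
class PivConfig:
    """Interrogation settings for PIV.

    Attributes
    ----------
    window : int
        Interrogation window side, px; a power of two >= 16.
    overlap_fraction : float
        Fractional overlap between adjacent windows, in [0, 1).
    mask_coverage_min : float
        Minimum fraction of valid (unmasked) pixels for a window to
        produce a vector.
    subpixel : str
        "gaussian" (3-point log-Gaussian) or "parabolic".
    pixel_size : float
        um per px.
    dt : float
        Frame interval, h.
    median_filter : bool
        Apply the 3-sigma local-median outlier filter to each field.
    """

    window: int = 32
    overlap_fraction: float = 0.5
    mask_coverage_min: float = 0.5
    subpixel: str = "gaussian"
    pixel_size: float = 1.0
    dt: float = 1.0
    median_filter: bool = True

    def __post_init__(self) -> None:
        w = self.window
        if w < 16 or (w & (w - 1)) != 0:
            raise ValueError(f"window must be a power of two >= 16, got {w}")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.pixel_size <= 0 or self.dt <= 0:
            raise ValueError("pixel_size and dt must be positive")
        if self.subpixel not in ("gaussian", "parabolic"):
            raise ValueError(f"unknown subpixel method {self.subpixel!r}")

    @property
    def step(self) -> int:
        return max(1, int(round(self.window * (1 - self.overlap_fraction))))


def _subpixel_offset(c_minus: float, c_0: float, c_plus: float, method: str) -> float:
    """Peak offset in (-1, 1) from three correlation samples."""
    if method == "gaussian" and c_minus > 0 and c_0 > 0 and c_plus > 0:
        lm, l0, lp = np.log(c_minus), np.log(c_0), np.log(c_plus)
        denom = 2.0 * (lm + lp - 2.0 * l0)
        if denom < 0:
            return float((lm - lp) / denom)
    denom = 2.0 * (c_minus + c_plus - 2.0 * c_0)
    if denom < 0:
        return float((c_minus - c_plus) / denom)
    return 0.0


from functools import lru_cache


@lru_cache(maxsize=8)
def _taper_and_envelope(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Hann window taper and its circular autocorrelation (the envelope
    the taper imprints on the cross-correlation)."""
    w = np.outer(np.hanning(n), np.hanning(n))
    fw = np.fft.rfft2(w)
    env = np.fft.fftshift(np.fft.irfft2(np.conj(fw) * fw, w.shape))
    return w, np.maximum(env, 1e-3 * env.max())


_PATCH_DESIGN = None


def _paraboloid_peak(log_patch: np.ndarray | None) -> tuple[float, float] | None:
    """Peak offset from a 9-point log-paraboloid least-squares fit.

    Fits ``a0 + a1 x + a2 y + a3 x^2 + a4 y^2 + a5 xy`` to the 3x3 log
    correlation patch (a 2D Gaussian peak is exactly this form); returns
    None when the patch is unusable or the stationary point is not an
    interior maximum, so the caller can fall back to per-axis fits.
    """
    global _PATCH_DESIGN
    if log_patch is None or not np.all(np.isfinite(log_patch)):
        return None
    if _PATCH_DESIGN is None:
        yy, xx = np.mgrid[-1:2, -1:2]
        a = np.column_stack([np.ones(9), xx.ravel(), yy.ravel(),
                             xx.ravel() ** 2, yy.ravel() ** 2, (xx * yy).ravel()])
        _PATCH_DESIGN = np.linalg.pinv(a)
    c0, c1, c2, c3, c4, c5 = _PATCH_DESIGN @ log_patch.ravel()
    hess = np.array([[2 * c3, c5], [c5, 2 * c4]])
    if np.linalg.det(hess) <= 0 or hess[0, 0] >= 0:
        return None
    off = np.linalg.solve(hess, [-c1, -c2])
    if np.any(np.abs(off) >= 1):
        return None
    return float(off[0]), float(off[1])


def _window_displacement(a: np.ndarray, b: np.ndarray, search: int,
                         method: str) -> tuple[float, float] | None:
    """Displacement (dx, dy) of features from a to b, px, or None if flat.

    Mean-subtracted windows are Hann-tapered before the FFT correlation
    (suppressing the bias from features cut at the window border) and the
    correlation is divided by the taper's own autocorrelation envelope,
    so the peak position is unbiased.
    """
    a = a - a.mean()
    b = b - b.mean()
    if a.std() == 0 or b.std() == 0:
        return None
    n = a.shape[0]
    w, env = _taper_and_envelope(n)
    fa = np.fft.rfft2(a * w)
    fb = np.fft.rfft2(b * w)
    # corr(s) = sum_x a(x) b(x + s): peak at s = displacement of features
    corr = np.fft.fftshift(np.fft.irfft2(np.conj(fa) * fb, a.shape)) / env
    c = n // 2  # zero-lag index after shift

    lo, hi = c - search, c + search + 1
    region = corr[lo:hi, lo:hi]
    iy, ix = np.unravel_index(np.argmax(region), region.shape)
    py = min(max(iy + lo, 1), n - 2)
    px = min(max(ix + lo, 1), n - 2)
    dy = float(py - c)
    dx = float(px - c)
    if method == "gaussian":
        off = _paraboloid_peak(np.log(corr[py - 1 : py + 2, px - 1 : px + 2])
                               if np.all(corr[py - 1 : py + 2, px - 1 : px + 2] > 0)
                               else None)
        if off is not None:
            return dx + off[0], dy + off[1]
    dx += _subpixel_offset(corr[py, px - 1], corr[py, px], corr[py, px + 1], method)
    dy += _subpixel_offset(corr[py - 1, px], corr[py, px], corr[py + 1, px], method)
    return dx, dy


def piv_pair(img_a: np.ndarray, img_b: np.ndarray, cfg: PivConfig,
             mask: np.ndarray | None = None, t: float = 0.0) -> VectorField:
    """Velocity field between two grayscale frames.

    Parameters
    ----------
    img_a, img_b : ndarray
        Grayscale frames of identical shape, at least 2x the window size.
    cfg : PivConfig
    mask : ndarray of bool, optional
        Analysis region (True = inside); windows with valid-pixel
        fraction below ``cfg.mask_coverage_min`` are masked out.
    t : float
        Acquisition time of the first frame, h.

    Returns
    -------
    VectorField
        u, v in um/h at window-center coordinates.
    """
    img_a = np.asarray(img_a, dtype=float)
    img_b = np.asarray(img_b, dtype=float)
    if img_a.shape != img_b.shape:
        raise ValueError("frames must have the same shape")
    h, w = img_a.shape
    win = cfg.window
    if h < 2 * win or w < 2 * win:
        raise ValueError(f"frames must be at least 2x the window ({win} px)")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != img_a.shape:
            raise ValueError("mask shape must match frames")

    step = cfg.step
    search = max(1, win // 4)
    # a `search` margin keeps integer-offset windows inside the frame
    margin = search if (h - win - 2 * search >= 0 and w - win - 2 * search >= 0) else 0
    ys = np.arange(margin, h - win - margin + 1, step)
    xs = np.arange(margin, w - win - margin + 1, step)
    u = np.zeros((ys.size, xs.size))
    v = np.zeros((ys.size, xs.size))
    valid = np.zeros((ys.size, xs.size), dtype=bool)

    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            if mask is not None:
                cov = mask[y0 : y0 + win, x0 : x0 + win].mean()
                if cov < cfg.mask_coverage_min:
                    continue
            win_a = img_a[y0 : y0 + win, x0 : x0 + win]
            # multi-pass with integer window offset: re-correlate against
            # the offset window until only a subpixel remainder is left,
            # which removes the loss-of-pairs bias (it grows with the
            # residual displacement)
            ox = oy = 0
            d = None
            for _ in range(4):
                yb = min(max(y0 + oy, 0), h - win)
                xb = min(max(x0 + ox, 0), w - win)
                ox, oy = xb - x0, yb - y0
                rem = _window_displacement(
                    win_a, img_b[yb : yb + win, xb : xb + win],
                    search, cfg.subpixel,
                )
                if rem is None:
                    break
                d = (ox + rem[0], oy + rem[1])
                rx, ry = int(round(rem[0])), int(round(rem[1]))
                if rx == 0 and ry == 0:
                    break
                ox += rx
                oy += ry
            if d is None:
                continue
            u[i, j] = d[0] * cfg.pixel_size / cfg.dt
            v[i, j] = d[1] * cfg.pixel_size / cfg.dt
            valid[i, j] = True

    field = VectorField(
        grid_x=(xs + (win - 1) / 2.0) * cfg.pixel_size,
        grid_y=(ys + (win - 1) / 2.0) * cfg.pixel_size,
        u=u, v=v, mask=valid, pixel_size=cfg.pixel_size, dt=cfg.dt, t=t,
    )
    if cfg.median_filter:
        field = median_filter_outliers(field)
    return field


def median_filter_outliers(field: VectorField, nsigma: float = 3.0,
                           floor: float = 0.0) -> VectorField:
    """Replace vectors far from the local median (normalized-median test).

    For each valid node the median and the median absolute deviation
    (MAD) of its valid 3x3 neighbors (excluding itself) form a robust
    residual ``|v - med| / (MAD + floor)``; vectors above ``nsigma`` are
    replaced by the neighbor median.  ``floor`` (in field units) guards
    against zero MAD on noiseless data; it defaults to a small fraction
    of the field's velocity scale.
    """
    u, v, m = field.u.copy(), field.v.copy(), field.mask
    ny, nx = m.shape
    if floor <= 0:
        scale = np.hypot(field.u[m], field.v[m]).max() if m.any() else 1.0
        floor = 1e-3 * max(scale, 1e-30)
    for comp in (u, v):
        out = comp.copy()
        for i in range(ny):
            for j in range(nx):
                if not m[i, j]:
                    continue
                sl = (slice(max(0, i - 1), i + 2), slice(max(0, j - 1), j + 2))
                nb = comp[sl][m[sl]].ravel().tolist()
                nb.remove(comp[i, j])  # drop the center once
                if len(nb) < 3:
                    continue
                nb = np.asarray(nb)
                med = np.median(nb)
                mad = np.median(np.abs(nb - med))
                if abs(comp[i, j] - med) > nsigma * (mad + floor):
                    out[i, j] = med
        comp[...] = out
    return VectorField(
        grid_x=field.grid_x, grid_y=field.grid_y, u=u, v=v, mask=m,
        pixel_size=field.pixel_size, dt=field.dt, t=field.t, units=field.units,
    )


def piv_movie(stack: np.ndarray | Sequence[np.ndarray], cfg: PivConfig,
              masks: Sequence[np.ndarray] | None = None,
              t0: float = 0.0) -> list[VectorField]:
    """PIV over consecutive frame pairs of an image stack.

    Frame ``k``'s mask is applied to the (k, k+1) pair, matching the
    contact-area segmentation convention of using the same mask for
    consecutive frames.
    """
    frames = [np.asarray(f, dtype=float) for f in stack]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    if masks is not None and len(masks) < len(frames) - 1:
        raise ValueError("need a mask for every frame pair")
    fields = []
    for k in range(len(frames) - 1):
        mask = masks[k] if masks is not None else None
        fields.append(piv_pair(frames[k], frames[k + 1], cfg, mask=mask,
                               t=t0 + k * cfg.dt))
    return fields
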