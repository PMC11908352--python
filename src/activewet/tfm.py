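"""Traction-force microscopy: Boussinesq forward operator and FTTC inversion.

The substrate is a semi-infinite, homogeneous, isotropic elastic
half-space (soft PDMS, default E = 15 kPa, nu = 0.5).  In Fourier space
the surface displacement u(q) produced by a surface traction T(q) is
u = K(q) T with the Boussinesq kernel

    K(q) = 2 (1 + nu) / (E q^3) * [[ (1-nu) q^2 + nu qy^2,  -nu qx qy ],
                                   [ -nu qx qy,  (1-nu) q^2 + nu qx^2 ]]

(E in Pa, q in 1/um, u in um, T in Pa).  The inverse problem (FTTC) is
solved mode by mode with 0th-order Tikhonov regularization,

    T = (K^T K + lambda^2 I)^-1 K^T u,

which at lambda = 0 is the direct inversion.  The q = 0 mode is
undefined (a rigid substrate shift) and is set to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import griddata

from .fields import VectorField

__all__ = [
    "ElasticSubstrate",
    "TractionMap",
    "forward_displacement",
    "fttc",
    "interpolate_to_grid",
    "select_lambda_lcurve",
]


@dataclass(frozen=True)
class ElasticSubstrate:
    """Linear elastic half-space.

    Attributes
    ----------
    E : float
        Young's modulus, kPa (15 kPa soft PDMS by default).
    nu : float
        Poisson ratio; 0.5 for incompressible PDMS.
    """

    E: float = 15.0
    nu: float = 0.5

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not 0 <= self.nu <= 0.5:
            raise ValueError("nu must be in [0, 0.5]")

    @property
    def E_pa(self) -> float:
        return self.E * 1e3


@dataclass
class TractionMap:
    """Traction components (Pa) on a regular grid.

    ``lam`` records the Tikhonov weight used to produce the map (NaN for
    forward-model inputs).
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    tx: np.ndarray
    ty: np.ndarray
    lam: float = float("nan")

    def __post_init__(self) -> None:
        self.grid_x = np.asarray(self.grid_x, dtype=float)
        self.grid_y = np.asarray(self.grid_y, dtype=float)
        self.tx = np.asarray(self.tx, dtype=float)
        self.ty = np.asarray(self.ty, dtype=float)
        shape = (self.grid_y.size, self.grid_x.size)
        if self.tx.shape != shape or self.ty.shape != shape:
            raise ValueError("tx, ty must have shape (len(grid_y), len(grid_x))")
        if not (np.all(np.isfinite(self.tx)) and np.all(np.isfinite(self.ty))):
            raise ValueError("traction components must be finite")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.tx, self.ty)

    def as_field(self) -> VectorField:
        """View the traction map as a VectorField (units Pa) for profile ops."""
        return VectorField(
            grid_x=self.grid_x, grid_y=self.grid_y, u=self.tx, v=self.ty,
            mask=np.ones_like(self.tx, dtype=bool), units="Pa",
        )


def _check_regular(grid: np.ndarray) -> float:
    d = np.diff(grid)
    if grid.size < 2 or not np.allclose(d, d[0]):
        raise ValueError("grid must be regular (uniform spacing)")
    return float(d[0])


def _kernel(shape: tuple[int, int], dx: float, dy: float,
            substrate: ElasticSubstrate):
    """Boussinesq kernel components on the FFT frequency grid.

    Returns (kxx, kxy, kyy, nonzero) with the q = 0 entry flagged.
    """
    ny, nx = shape
    qx = 2 * np.pi * np.fft.fftfreq(nx, d=dx)[None, :]
    qy = 2 * np.pi * np.fft.fftfreq(ny, d=dy)[:, None]
    q2 = qx**2 + qy**2
    nonzero = q2 > 0
    q = np.sqrt(np.where(nonzero, q2, 1.0))
    e, nu = substrate.E_pa, substrate.nu
    pref = 2.0 * (1.0 + nu) / (e * q**3)
    kxx = pref * ((1.0 - nu) * q2 + nu * qy**2)
    kyy = pref * ((1.0 - nu) * q2 + nu * qx**2)
    kxy = pref * (-nu * qx * qy)
    for k in (kxx, kyy, kxy):
        k[~nonzero] = 0.0
    return kxx, kxy, kyy, nonzero


def forward_displacement(traction: TractionMap,
                         substrate: ElasticSubstrate) -> VectorField:
    """Surface displacement field (um) produced by a traction map.

    Periodic forward operator: u(q) = K(q) T(q) mode by mode.  The mean
    (q = 0) displacement is undefined on a half-space and set to zero, so
    inputs should have (close to) zero net force.
    """
    dx = _check_regular(traction.grid_x)
    dy = _check_regular(traction.grid_y)
    kxx, kxy, kyy, _ = _kernel(traction.tx.shape, dx, dy, substrate)
    ftx = np.fft.fft2(traction.tx)
    fty = np.fft.fft2(traction.ty)
    ux = np.fft.ifft2(kxx * ftx + kxy * fty).real
    uy = np.fft.ifft2(kxy * ftx + kyy * fty).real
    return VectorField(
        grid_x=traction.grid_x, grid_y=traction.grid_y, u=ux, v=uy,
        mask=np.ones_like(ux, dtype=bool), units="um",
    )


def fttc(displacement: VectorField, substrate: ElasticSubstrate,
         lam: float = 0.0, taper: bool = False) -> TractionMap:
    """Fourier-transform traction cytometry with 0th-order Tikhonov.

    Parameters
    ----------
    displacement : VectorField
        Fully gridded displacement field, um (grid scattered data first
        with :func:`interpolate_to_grid`); all nodes must be valid.
    substrate : ElasticSubstrate
    lam : float
        Tikhonov weight lambda >= 0 (units of the kernel, um/Pa);
        0 gives the direct inversion.
    taper : bool
        Mean-subtract and Hann-taper the displacement before the FFT to
        suppress periodicity artifacts on non-periodic data.  Off by
        default so that the forward/inverse pair is exactly mutually
        inverse.

    Returns
    -------
    TractionMap
        Tractions in Pa.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if not displacement.mask.all():
        raise ValueError("displacement field has invalid nodes; grid it first")
    dx = _check_regular(displacement.grid_x)
    dy = _check_regular(displacement.grid_y)
    u, v = displacement.u, displacement.v
    if taper:
        ny, nx = u.shape
        win = np.outer(np.hanning(ny), np.hanning(nx))
        u = (u - u.mean()) * win
        v = (v - v.mean()) * win

    kxx, kxy, kyy, nonzero = _kernel(u.shape, dx, dy, substrate)
    fu = np.fft.fft2(u)
    fv = np.fft.fft2(v)
    # per-mode 2x2 solve of (K^T K + lam^2 I) T = K^T u; K is symmetric
    a11 = kxx**2 + kxy**2 + lam**2
    a12 = kxy * (kxx + kyy)
    a22 = kyy**2 + kxy**2 + lam**2
    b1 = kxx * fu + kxy * fv
    b2 = kxy * fu + kyy * fv
    det = a11 * a22 - a12**2
    det = np.where(nonzero, det, 1.0)
    ftx = np.where(nonzero, (a22 * b1 - a12 * b2) / det, 0.0)
    fty = np.where(nonzero, (a11 * b2 - a12 * b1) / det, 0.0)
    tx = np.fft.ifft2(ftx).real
    ty = np.fft.ifft2(fty).real
    return TractionMap(grid_x=displacement.grid_x, grid_y=displacement.grid_y,
                       tx=tx, ty=ty, lam=lam)


def select_lambda_lcurve(displacement: VectorField, substrate: ElasticSubstrate,
                         lambdas: np.ndarray | None = None,
                         taper: bool = False) -> float:
    """Tikhonov weight at the L-curve corner (maximum curvature).

    Sweeps ``lambdas`` (log-spaced around the kernel scale by default),
    records log residual norm vs log solution norm, and returns the
    lambda of maximum discrete curvature.
    """
    dx = _check_regular(displacement.grid_x)
    if lambdas is None:
        # kernel magnitude scale ~ 2(1+nu)/(E q_min)
        qmin = 2 * np.pi / (displacement.grid_x[-1] - displacement.grid_x[0] + dx)
        k0 = 2 * (1 + substrate.nu) / (substrate.E_pa * qmin)
        lambdas = k0 * np.logspace(-4, 1, 25)
    lambdas = np.asarray(lambdas, dtype=float)
    rho = np.empty(len(lambdas))
    eta = np.empty(len(lambdas))
    for i, lam in enumerate(lambdas):
        tm = fttc(displacement, substrate, lam=lam, taper=taper)
        pred = forward_displacement(tm, substrate)
        rho[i] = np.sqrt(np.mean((pred.u - displacement.u) ** 2 +
                                 (pred.v - displacement.v) ** 2))
        eta[i] = np.sqrt(np.mean(tm.tx**2 + tm.ty**2))
    # discard the under-regularized plateau where the residual has not yet
    # risen above the noise floor; its wiggles produce spurious curvature
    keep = rho > 2.0 * rho.min()
    if keep.sum() >= 5:
        lambdas, rho, eta = lambdas[keep], rho[keep], eta[keep]
    x = np.log(np.maximum(rho, 1e-300))
    y = np.log(np.maximum(eta, 1e-300))
    dx1 = np.gradient(x)
    dy1 = np.gradient(y)
    ddx = np.gradient(dx1)
    ddy = np.gradient(dy1)
    curv = (dx1 * ddy - dy1 * ddx) / np.maximum((dx1**2 + dy1**2) ** 1.5, 1e-300)
    return float(lambdas[int(np.argmax(curv))])


def interpolate_to_grid(points, grid_x, grid_y) -> VectorField:
    """Linear interpolation of scattered displacements onto a regular grid.

    Parameters
    ----------
    points : array_like or DataFrame
        Columns (x_um, y_um, ux_um, uy_um); at least 4 non-collinear
        positions.
    grid_x, grid_y : array_like
        Target grid coordinates, um.

    Returns
    -------
    VectorField
        Displacements (um); nodes outside the convex hull are masked.
    """
    arr = np.asarray(points, dtype=float)
    if hasattr(points, "to_numpy"):
        arr = points.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 4 or arr.shape[0] < 4:
        raise ValueError("need >= 4 points with columns (x, y, ux, uy)")
    xy = arr[:, :2]
    if np.linalg.matrix_rank(xy - xy.mean(axis=0)) < 2:
        raise ValueError("points are collinear")
    grid_x = np.asarray(grid_x, dtype=float)
    grid_y = np.asarray(grid_y, dtype=float)
    gx, gy = np.meshgrid(grid_x, grid_y)
    ux = griddata(xy, arr[:, 2], (gx, gy), method="linear")
    uy = griddata(xy, arr[:, 3], (gx, gy), method="linear")
    mask = np.isfinite(ux) & np.isfinite(uy)
    ux = np.where(mask, ux, 0.0)
    uy = np.where(mask, uy, 0.0)
    return VectorField(grid_x=grid_x, grid_y=grid_y, u=ux, v=uy, mask=mask,
                       units="um")
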