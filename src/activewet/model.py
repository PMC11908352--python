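"""Closed-form and numerical solutions of the active polar fluid model.

The tissue is a 2D active polar fluid with a radial polarity field
``p(r)`` and a radial velocity field ``v(r)`` on an annulus
``R1 <= r <= R`` (``R1 = 0`` recovers the full disk).

Polarity relaxes fast and obeys ``Lc^2 laplacian(p) = p`` with ``p(R) = 1``
at the fully polarized edge and ``p(0) = 0`` by symmetry; on the disk its
solution is the modified-Bessel ratio ``p(r) = I1(r/Lc) / I1(R/Lc)``.

Force balance between the traction exerted on the substrate and the
divergence of the internal stress, with the constitutive law
``sigma = eta (grad v + grad v^T) - zeta p p``, reduces (after dividing
through by ``2 eta`` and absorbing material constants into the composite
parameters ``A`` and ``B``) to

    v'' + v'/r - v/r^2 = -(B/2) [ (p^2)' + p^2/r ] - (A/2) p

with boundary conditions ``v(R1) = 0`` (no flow at the solid core) and
``sigma_rr(R) = 0`` (stress-free spreading front), i.e.
``2 v'(R) + B p(R)^2 = 0``.

The closed-form solution implemented here is

    v(r) = -(A Lc^2 / 2) I1(x)/I1(X)
           - (B Lc / 4) I0(x) I1(x) / I1(X)^2
           + c1 r + c2 / r,          x = r/Lc, X = R/Lc,

where the particular solutions follow from the exact indefinite
integrals ``int I1(x)^2 / x dx = (I0^2 - I1^2)/2`` and
``int x (I0^2 + I1^2) dx = x I0 I1``, and ``(c1, c2)`` are fixed by the
two boundary conditions (a 2x2 linear solve).  A collocation boundary-
value solver provides an independent numerical oracle.

All Bessel evaluations use exponentially scaled ``ive`` so that large
``R/Lc`` (short nematic length) cannot overflow.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_bvp
from scipy.special import ive

from .params import ModelParams, TractionFitParams

__all__ = [
    "polarity_profile",
    "velocity_profile",
    "velocity_derivative",
    "stress_rr",
    "velocity_profile_numeric",
    "traction_profile",
]

# Inner collocation boundary placed at _DISK_EPS * R when R1 == 0; the
# regular solution behaves as v ~ c r near the axis, so the mixed
# regularity condition a v'(a) - v(a) = 0 is accurate to O((a/R)^2).
_DISK_EPS = 1e-6


def _bessel_ratio_i1(x, X):
    """I1(x) / I1(X) without overflow, valid for x, X >= 0."""
    return ive(1, x) / ive(1, X) * np.exp(x - X)


def polarity_profile(r, Lc: float, R: float):
    """Radial polarity p(r) = I1(r/Lc) / I1(R/Lc) on the disk of radius R.

    Parameters
    ----------
    r : array_like
        Radius, um, with ``0 <= r <= R``.
    Lc : float
        Nematic length, um, positive.
    R : float
        Monolayer radius, um.

    Returns
    -------
    ndarray or float
        Dimensionless polarity in [0, 1]; exactly 0 at the center and
        exactly 1 at the edge.
    """
    if Lc <= 0:
        raise ValueError(f"Lc must be positive, got {Lc}")
    if R <= 0:
        raise ValueError(f"R must be positive, got {R}")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > R):
        raise ValueError("r must lie in [0, R]")
    out = _bessel_ratio_i1(r / Lc, R / Lc)
    return out if out.ndim else float(out)


def polarity_derivative(r, Lc: float, R: float):
    """dp/dr of the disk polarity solution (p'(0) = 1/(2 Lc I1(R/Lc)))."""
    r = np.asarray(r, dtype=float)
    x = r / Lc
    X = R / Lc
    i0 = ive(0, x)
    i1 = ive(1, x)
    # I1'(x) = I0(x) - I1(x)/x, with the x -> 0 limit 1/2.
    i1p = np.where(x > 0, i0 - np.divide(i1, x, out=np.zeros_like(x), where=x > 0), 0.5)
    out = i1p / ive(1, X) * np.exp(x - X) / Lc
    return out if out.ndim else float(out)


def _particular(r, params: ModelParams):
    """Particular solution v_p(r) of the forced radial force balance."""
    A, B, Lc, R = params.A, params.B, params.Lc, params.R
    x = np.asarray(r, dtype=float) / Lc
    X = R / Lc
    i0 = ive(0, x)
    i1 = ive(1, x)
    i1X = ive(1, X)
    eA = np.exp(x - X)
    eB = np.exp(2.0 * (x - X))
    return (-(A * Lc**2 / 2.0) * i1 / i1X * eA
            - (B * Lc / 4.0) * i0 * i1 / i1X**2 * eB)


def _particular_derivative(r, params: ModelParams):
    """d v_p / dr."""
    A, B, Lc, R = params.A, params.B, params.Lc, params.R
    x = np.asarray(r, dtype=float) / Lc
    X = R / Lc
    i0 = ive(0, x)
    i1 = ive(1, x)
    i1X = ive(1, X)
    i1p = np.where(x > 0, i0 - np.divide(i1, x, out=np.zeros_like(x), where=x > 0), 0.5)
    eA = np.exp(x - X)
    eB = np.exp(2.0 * (x - X))
    dA = -(A * Lc / 2.0) * i1p / i1X * eA
    dB = -(B / 4.0) * (i1**2 + i0 * i1p) / i1X**2 * eB
    return dA + dB


def _homogeneous_coeffs(params: ModelParams) -> tuple[float, float]:
    """Coefficients (c1, c2) of the homogeneous part c1 r + c2 / r.

    Fixed by v(R1) = 0 and sigma_rr(R) = 0, i.e. v'(R) = -B/2 (p(R) = 1).
    For the disk (R1 = 0) regularity forces c2 = 0.
    """
    R, R1, B = params.R, params.R1, params.B
    rhs_edge = -B / 2.0 - float(_particular_derivative(R, params))
    if R1 == 0.0:
        return rhs_edge, 0.0
    rhs_core = -float(_particular(R1, params))
    m = np.array([[R1, 1.0 / R1], [1.0, -1.0 / R**2]])
    c1, c2 = np.linalg.solve(m, np.array([rhs_core, rhs_edge]))
    return float(c1), float(c2)


def velocity_profile(r, params: ModelParams):
    """Radial velocity v(r) of the annular solution, um/h.

    Parameters
    ----------
    r : array_like
        Radius, um, with ``R1 <= r <= R``.
    params : ModelParams
        Composite parameters (A, B, Lc, R, R1).

    Returns
    -------
    ndarray or float
        Radial velocity, um/h.  Satisfies ``v(R1) = 0`` and the
        stress-free edge condition exactly (to rounding).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < params.R1) or np.any(r > params.R):
        raise ValueError("r must lie in [R1, R]")
    c1, c2 = _homogeneous_coeffs(params)
    safe_r = np.where(r > 0, r, 1.0)  # c2 is 0 whenever r = 0 is admissible
    out = _particular(r, params) + c1 * r + c2 / safe_r
    return out if out.ndim else float(out)


def velocity_derivative(r, params: ModelParams):
    """dv/dr of the annular solution, 1/h."""
    r = np.asarray(r, dtype=float)
    if np.any(r < params.R1) or np.any(r > params.R):
        raise ValueError("r must lie in [R1, R]")
    c1, c2 = _homogeneous_coeffs(params)
    safe_r = np.where(r > 0, r, 1.0)
    out = _particular_derivative(r, params) + c1 - c2 / safe_r**2
    return out if out.ndim else float(out)


def stress_rr(r, params: ModelParams):
    """Viscosity-normalized radial stress sigma_rr / eta = 2 v'(r) + B p(r)^2, 1/h.

    Vanishes at the free edge r = R by construction.
    """
    p = polarity_profile(r, params.Lc, params.R)
    return 2.0 * velocity_derivative(r, params) + params.B * np.asarray(p) ** 2


def velocity_profile_numeric(params: ModelParams, r_grid, tol: float = 1e-10,
                             max_nodes: int = 200_000):
    """Collocation boundary-value solution of the radial force balance.

    Independent numerical oracle for :func:`velocity_profile`: solves

        v'' = -v'/r + v/r^2 - (B/2)[(p^2)' + p^2/r] - (A/2) p

    with ``v(R1) = 0`` and ``2 v'(R) + B p(R)^2 = 0``.  For the disk
    (``R1 = 0``) the inner boundary is moved to ``1e-6 R`` with the
    regularity condition ``a v'(a) = v(a)``.

    Parameters
    ----------
    params : ModelParams
    r_grid : array_like
        Strictly increasing radii inside [R1, R] (or [0, R] on the disk).
    tol, max_nodes :
        Passed to :func:`scipy.integrate.solve_bvp`.

    Returns
    -------
    ndarray
        Radial velocity on ``r_grid``, um/h.

    Raises
    ------
    RuntimeError
        If the collocation solver does not converge; the solver message
        and residual are included.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if r_grid.ndim != 1 or r_grid.size < 2 or np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid must be a strictly increasing 1D array")
    if r_grid[0] < params.R1 or r_grid[-1] > params.R:
        raise ValueError("r_grid must lie within [R1, R]")

    A, B, Lc, R, R1 = params.A, params.B, params.Lc, params.R, params.R1

    def p(r):
        return _bessel_ratio_i1(r / Lc, R / Lc)

    def rhs(r, y):
        pr = p(r)
        ppr = polarity_derivative(r, Lc, R)
        force = -(B / 2.0) * (2.0 * pr * ppr + pr**2 / r) - (A / 2.0) * pr
        return np.vstack([y[1], -y[1] / r + y[0] / r**2 + force])

    # a core far below the collocation resolution is treated as the disk
    disk = R1 <= _DISK_EPS * R
    a = _DISK_EPS * R if disk else R1

    def bc(ya, yb):
        inner = a * ya[1] - ya[0] if disk else ya[0]
        return np.array([inner, 2.0 * yb[1] + B * p(R) ** 2])

    mesh = np.linspace(a, R, 201)
    sol = solve_bvp(rhs, bc, mesh, np.zeros((2, mesh.size)), tol=tol,
                    max_nodes=max_nodes)
    if sol.status != 0:
        raise RuntimeError(
            f"BVP solver failed (status {sol.status}): {sol.message}; "
            f"max residual {np.max(sol.rms_residuals):.3e}"
        )
    eval_r = np.clip(r_grid, a, R)  # r < a only in the disk case, where v ~ c r
    out = sol.sol(eval_r)[0]
    if disk:
        small = r_grid < a
        if np.any(small):
            out = out.copy()
            out[small] *= r_grid[small] / a
    return out


def traction_profile(r, fit: TractionFitParams):
    """Radial traction Tr(r) = -T0 I1(r/Lc) / I1(R/Lc).

    Sign convention: the traction the cells exert on the substrate points
    inward (centripetal), so the radial component is negative and its
    magnitude grows monotonically toward the edge, reaching ``-T0`` at
    ``r = R``.

    Parameters
    ----------
    r : array_like
        Radius, um, in [0, R].
    fit : TractionFitParams

    Returns
    -------
    ndarray or float
        Radial traction in the units of ``T0``.
    """
    return -fit.T0 * polarity_profile(r, fit.Lc, fit.R)
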