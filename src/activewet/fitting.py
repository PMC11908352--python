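"""Profile-fitting estimators for the polar-fluid model.

Statsmodels-style model objects: construct from a :class:`RadialProfile`,
call ``fit()``, get a :class:`FitResult` with estimates, standard errors
from the Jacobian, the fit window, and convergence diagnostics.

Velocity profiles are fitted with ``R`` fixed to the boundary value and
``(A, B, Lc, R1)`` free, over a window extending to 1.07x the position of
the profile peak (configurable); this trims the outermost bins, whose
azimuthal averages are corrupted by the ragged spreading front.

Traction profiles are fitted with ``(T0, Lc)`` free, with ``R`` set to the
position of the maximum traction magnitude and the outer region beyond it
discarded (poorly attached protrusions and long-range substrate
deformation contaminate it).
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.optimize import least_squares, nnls

from .fields import RadialProfile
from .model import traction_profile, velocity_profile
from .params import ModelParams, TractionFitParams
from .results import FitResult, stderr_from_jacobian

__all__ = [
    "VelocityProfileModel",
    "TractionProfileModel",
    "fit_velocity_profile",
    "fit_traction_profile",
]

_MIN_POINTS_VELOCITY = 8


def predict_velocity(r, params: ModelParams):
    """Model velocity with the solid-core convention v(r) = 0 for r < R1.

    Used during fitting, where trial values of R1 may exceed data radii;
    the flow inside the solid core is zero by assumption.
    """
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    inside = (r >= params.R1) & (r <= params.R)
    if np.any(inside):
        out[inside] = velocity_profile(r[inside], params)
    return out


class VelocityProfileModel:
    """Nonlinear least squares of the annular velocity solution to a profile.

    Parameters
    ----------
    profile : RadialProfile
        Azimuthally averaged radial velocity (um/h vs um).
    R : float
        Outer radius, um, held fixed during the fit (the boundary value
        from segmentation).
    window_factor : float
        The fit window ends at ``window_factor * r_peak`` where ``r_peak``
        is the position of the profile maximum; default 1.07.
    """

    param_names = ("A", "B", "Lc", "R1")

    def __init__(self, profile: RadialProfile, R: float,
                 window_factor: float = 1.07) -> None:
        if R <= 0:
            raise ValueError("R must be positive")
        self.profile = profile
        self.R = float(R)
        self.window_factor = float(window_factor)
        if np.allclose(profile.value, 0.0):
            r_peak = float(profile.r_centers[-1])  # degenerate: keep all bins
        else:
            r_peak = float(profile.r_centers[np.argmax(profile.value)])
        hi = min(self.window_factor * r_peak, self.R)
        sel = profile.r_centers <= hi
        self.r = profile.r_centers[sel]
        self.y = profile.value[sel]
        self.window = (float(self.r[0]), float(self.r[-1])) if self.r.size else (0.0, 0.0)

    # -- initialization -------------------------------------------------
    def _init_r1(self) -> float:
        """First radius where the (3-bin smoothed) profile exceeds 10% of max."""
        y = self.y
        if y.size >= 3:
            y = np.convolve(y, np.ones(3) / 3.0, mode="same")
        above = self.r[y > 0.1 * y.max()]
        r1 = float(above[0]) if above.size else 0.0
        return min(max(r1, 0.0), 0.9 * self.R)

    def _linear_amplitudes(self, lc: float, r1: float) -> tuple[float, float, float]:
        """Best nonnegative (A, B) at fixed (Lc, R1), and the SSE.

        The solution (including both boundary conditions) is exactly
        linear in A and B, so the amplitude subproblem is a two-column
        nonnegative least squares.
        """
        fa = predict_velocity(self.r, ModelParams(A=1.0, B=0.0, Lc=lc,
                                                  R=self.R, R1=r1))
        fb = predict_velocity(self.r, ModelParams(A=0.0, B=1.0, Lc=lc,
                                                  R=self.R, R1=r1))
        design = np.column_stack([fa, fb])
        coef, _ = nnls(design, self.y)
        resid = design @ coef - self.y
        return float(coef[0]), float(coef[1]), float(resid @ resid)

    def _start_values(self) -> np.ndarray:
        """Global-search start: profiled grid over (Lc, R1).

        (A, B) are solved linearly at each grid node; the best node seeds
        the full nonlinear polish.  The data-driven R1 guess (10%-of-max
        rule) is included in the grid.
        """
        lc_grid = self.R * np.geomspace(0.05, 2.0, 12)
        r1_grid = np.unique(np.concatenate([
            np.linspace(0.0, 0.85 * self.R, 9), [self._init_r1()]]))
        best = None
        for lc, r1 in product(lc_grid, r1_grid):
            a, b, sse = self._linear_amplitudes(lc, r1)
            if best is None or sse < best[0]:
                best = (sse, np.array([max(a, 1e-12), max(b, 1e-12), lc, r1]))
        return best[1]

    def _multistarts(self) -> list[np.ndarray]:
        """Deterministic fallback starts over (Lc, R1) with linear (A, B)."""
        starts = []
        for lc_frac, r1_frac in product((0.1, 0.25, 0.5), (0.0, 0.3)):
            lc, r1 = lc_frac * self.R, r1_frac * self.R
            a, b, _ = self._linear_amplitudes(lc, r1)
            starts.append(np.array([max(a, 1e-12), max(b, 1e-12), lc, r1]))
        return starts[:5]

    # -- fitting --------------------------------------------------------
    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        a, b, lc, r1 = theta
        p = ModelParams(A=a, B=b, Lc=max(lc, 1e-9), R=self.R,
                        R1=min(max(r1, 0.0), self.R * (1 - 1e-9)))
        return predict_velocity(self.r, p) - self.y

    def fit(self, start: ModelParams | None = None) -> FitResult:
        """Run the bounded trust-region least squares.

        Non-convergence, too few window points, an all-zero profile, or
        an R1 estimate pinned at the outer radius are flagged via
        ``converged=False``; estimates are never silently clipped.
        """
        def flagged(msg: str) -> FitResult:
            return FitResult(
                params=dict.fromkeys(self.param_names, float("nan")),
                stderr=dict.fromkeys(self.param_names, float("nan")),
                window=self.window, residual_rms=float("nan"), converged=False,
                n_points=int(self.r.size), message=msg,
            )

        if np.allclose(self.y, 0.0):
            return flagged("profile is identically zero")
        if self.r.size < _MIN_POINTS_VELOCITY:
            return flagged(
                f"only {self.r.size} points in fit window "
                f"(need >= {_MIN_POINTS_VELOCITY})"
            )

        lb = np.array([0.0, 0.0, 1e-6 * self.R, 0.0])
        ub = np.array([np.inf, np.inf, np.inf, self.R * (1 - 1e-9)])
        if start is not None:
            starts = [np.array([start.A, start.B, start.Lc, start.R1])]
        else:
            starts = [self._start_values()]

        best = None
        for x0 in starts:
            res = least_squares(self._residuals, np.clip(x0, lb, ub),
                                bounds=(lb, ub), method="trf")
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None or not best.success:
            for x0 in self._multistarts():
                res = least_squares(self._residuals, np.clip(x0, lb, ub),
                                    bounds=(lb, ub), method="trf")
                if res.success and (best is None or res.cost < best.cost):
                    best = res
        if best is None:
            return flagged("optimizer failed to converge from all starts")

        est = dict(zip(self.param_names, best.x))
        se = stderr_from_jacobian(best.jac, best.fun)
        rms = float(np.sqrt(np.mean(best.fun**2)))
        result = FitResult(
            params={k: float(v) for k, v in est.items()},
            stderr=dict(zip(self.param_names, (float(s) for s in se))),
            window=self.window, residual_rms=rms, converged=True,
            n_points=int(self.r.size),
        )
        if est["R1"] >= self.R * (1 - 1e-6):
            result.converged = False
            result.message = "R1 bound active at R: no annular flow region"
        return result


class TractionProfileModel:
    """Two-parameter Bessel-profile fit of a radial traction profile.

    ``R`` is set to the radius of the maximum traction magnitude and the
    outer region discarded.  The model is fitted to the signed values with
    the profile's dominant sign, so either sign convention (inward-negative
    radial component or magnitudes) recovers the same ``(T0, Lc)``.
    """

    param_names = ("T0", "Lc")

    def __init__(self, profile: RadialProfile) -> None:
        self.profile = profile
        mag = np.abs(profile.value)
        i_max = int(np.argmax(mag))
        self.R = float(profile.r_centers[i_max])
        sel = profile.r_centers <= self.R
        self.r = profile.r_centers[sel]
        self.y = profile.value[sel]
        self.sign = -1.0 if self.y.sum() < 0 else 1.0
        self.window = (float(self.r[0]), float(self.r[-1])) if self.r.size else (0.0, 0.0)
        self._i_max = i_max

    def fit(self, start: TractionFitParams | None = None) -> FitResult:
        def flagged(msg: str) -> FitResult:
            return FitResult(
                params=dict.fromkeys(self.param_names, float("nan")),
                stderr=dict.fromkeys(self.param_names, float("nan")),
                window=self.window, residual_rms=float("nan"), converged=False,
                n_points=int(self.r.size), message=msg, extra={"R": self.R},
            )

        if self._i_max == 0 or self.r.size < 3:
            return flagged(
                "traction magnitude peaks at the innermost bin: no usable window"
            )
        t0_0 = abs(self.y[-1])
        lc_0 = self.R / 3.0
        if start is not None:
            t0_0, lc_0 = start.T0, start.Lc

        def resid(theta):
            fitp = TractionFitParams(T0=theta[0], Lc=max(theta[1], 1e-12), R=self.R)
            return self.sign * -traction_profile(self.r, fitp) - self.y

        res = least_squares(resid, x0=[max(t0_0, 1e-12), lc_0],
                            bounds=([0.0, 1e-6 * self.R], [np.inf, np.inf]))
        if not res.success:
            return flagged(f"optimizer failed: {res.message}")
        se = stderr_from_jacobian(res.jac, res.fun)
        return FitResult(
            params={"T0": float(res.x[0]), "Lc": float(res.x[1])},
            stderr={"T0": float(se[0]), "Lc": float(se[1])},
            window=self.window,
            residual_rms=float(np.sqrt(np.mean(res.fun**2))),
            converged=True, n_points=int(self.r.size), extra={"R": self.R},
        )


def fit_velocity_profile(profile: RadialProfile, R: float,
                         init: ModelParams | None = None,
                         window_factor: float = 1.07) -> FitResult:
    """Fit (A, B, Lc, R1) to a radial velocity profile with R fixed."""
    return VelocityProfileModel(profile, R=R, window_factor=window_factor).fit(start=init)


def fit_traction_profile(profile: RadialProfile,
                         init: TractionFitParams | None = None) -> FitResult:
    """Fit (T0, Lc) to a radial traction profile; R from the profile maximum.

    The fitted monolayer radius is reported in ``extra['R']``.
    """
    return TractionProfileModel(profile).fit(start=init)
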