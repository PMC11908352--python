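"""Scalar time-series fits: spreading, melting, wound coverage, fusion, recoil.

Every estimator consumes a :class:`KineticTrace` (a declared-unit (t, y)
series) and returns a :class:`FitResult`.  Linear fits are ordinary least
squares; nonlinear fits are bounded trust-region least squares with
standard errors from the Jacobian.

The fits implemented:

- contact-area spreading rate dA/dt (linear, gated to frames where the
  area exceeds the initial spheroid projection by >= 20%, over the first
  24 h);
- solid-core melting rate d(R1/R0)/dt (linear);
- wound-coverage two-segment regression (continuous two-piece line,
  exhaustive breakpoint search; the second slope is the maximal coverage
  rate after the lag phase);
- spheroid-fusion coalescence (r/R)^2 = a (1 - exp(-Gamma t)), with the
  amplitude ``a`` near 1 for complete fusion and < 1 for arrested
  coalescence;
- fusion-rate size scaling Gamma ~ (sigma/eta) / R0, estimated by
  regressing 1/Gamma on R0 through the origin;
- post-ablation vertex recoil f(t) = (r0/k)(1 - exp(-k t)) with r0 the
  initial recoil velocity;
- normalized apical-area response y(t_probe) - 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .results import FitResult, stderr_from_jacobian

__all__ = [
    "KineticTrace",
    "FusionPair",
    "TwoSegmentFit",
    "fit_spreading_rate",
    "fit_melting_rate",
    "two_segment_regression",
    "fit_fusion",
    "fit_fusion_scaling",
    "fit_recoil",
    "apical_response",
    "COMPLETE_FUSION_AMPLITUDE",
]

# amplitude threshold separating complete fusion from arrested coalescence
COMPLETE_FUSION_AMPLITUDE = 0.9


@dataclass
class KineticTrace:
    """A (time, value) series with declared units.

    ``t`` must be strictly increasing and ``y`` finite.
    """

    t: np.ndarray
    y: np.ndarray
    t_units: str = "h"
    y_units: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be 1D arrays of equal length")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y must be finite")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class FusionPair:
    """One fusion experiment: spheroid radius plus its fitted coalescence.

    Attributes
    ----------
    R0 : float
        Initial spheroid radius, um.
    gamma : float
        Fitted fusion rate, 1/h (or 1/s, consistently across pairs).
    amplitude : float
        Fitted plateau (r/R)^2 at infinite time.
    trace : KineticTrace or None
        The underlying normalized neck trace, if kept.
    """

    R0: float
    gamma: float
    amplitude: float
    trace: KineticTrace | None = None

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if not 0 <= self.amplitude <= 1.2:
            raise ValueError("amplitude must be in [0, 1.2]")


def _ols_result(t: np.ndarray, y: np.ndarray, names=("slope", "intercept")) -> FitResult:
    res = stats.linregress(t, y)
    pred = res.intercept + res.slope * t
    return FitResult(
        params={names[0]: float(res.slope), names[1]: float(res.intercept)},
        stderr={names[0]: float(res.stderr), names[1]: float(res.intercept_stderr)},
        window=(float(t[0]), float(t[-1])),
        residual_rms=float(np.sqrt(np.mean((y - pred) ** 2))),
        converged=True, n_points=int(t.size),
    )


def fit_spreading_rate(trace: KineticTrace, t_max: float = 24.0,
                       start_gate: float = 0.20,
                       A0: float | None = None) -> FitResult:
    """Early-stage spreading rate dA/dt from the contact-area trace.

    Only frames where the area has exceeded the initial spheroid
    projection ``A0`` by at least ``start_gate`` (20% by default) and with
    ``t <= t_max`` (24 h) enter the ordinary least squares
    ``A(t) = (dA/dt) t + c``.

    Parameters
    ----------
    trace : KineticTrace
        Contact area vs time (um^2 vs h).
    t_max : float
        Upper time limit of the fit, h.
    start_gate : float
        Required fractional excess over A0 before a frame is used.
    A0 : float, optional
        Initial spheroid projected area; defaults to the first sample.

    Returns
    -------
    FitResult over ('dA_dt', 'intercept'); flagged when fewer than 5
    frames pass the gate.
    """
    a0 = float(trace.y[0]) if A0 is None else float(A0)
    sel = (trace.y > (1.0 + start_gate) * a0) & (trace.t <= t_max)
    if sel.sum() < 5:
        return FitResult(
            params={"dA_dt": float("nan"), "intercept": float("nan")},
            stderr={"dA_dt": float("nan"), "intercept": float("nan")},
            window=(float(trace.t[0]), float(trace.t[-1])),
            residual_rms=float("nan"), converged=False, n_points=int(sel.sum()),
            message=f"only {int(sel.sum())} gated points (need >= 5)",
        )
    return _ols_result(trace.t[sel], trace.y[sel], names=("dA_dt", "intercept"))


def fit_melting_rate(trace: KineticTrace) -> FitResult:
    """Normalized core melting rate d(R1/R0)/dt by ordinary least squares."""
    if len(trace) < 4:
        raise ValueError("need at least 4 points")
    if np.ptp(trace.t) == 0:
        raise ValueError("degenerate time support")
    return _ols_result(trace.t, trace.y, names=("rate", "intercept"))


@dataclass
class TwoSegmentFit:
    """Continuous two-piece linear fit of a coverage curve."""

    slope1: float
    slope2: float
    breakpoint: float
    breakpoint_index: int
    intercept: float
    sse: float

    def __iter__(self):
        return iter((self.slope1, self.slope2, self.breakpoint))


def two_segment_regression(trace: KineticTrace, min_per_segment: int = 3) -> TwoSegmentFit:
    """Continuous two-piece linear regression with exhaustive breakpoint search.

    For every interior sample time ``t_k`` leaving at least
    ``min_per_segment`` points per segment, the continuous model
    ``y = c + b1 t + (b2 - b1) max(t - t_k, 0)`` is fitted by linear least
    squares; the breakpoint minimizing the total SSE wins, ties (within
    rounding) going to the earliest breakpoint.
    """
    t, y = trace.t, trace.y
    n = t.size
    if n < 2 * min_per_segment or n < 8:
        raise ValueError(
            f"need >= {max(8, 2 * min_per_segment)} points with "
            f">= {min_per_segment} per segment"
        )
    scale = float(np.sum((y - y.mean()) ** 2)) + 1e-300
    tol = 1e-10 * scale
    best: TwoSegmentFit | None = None
    for k in range(min_per_segment - 1, n - min_per_segment):
        tb = t[k]
        X = np.column_stack([np.ones(n), t, np.maximum(t - tb, 0.0)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((X @ coef - y) ** 2))
        if best is None or sse < best.sse - tol:
            best = TwoSegmentFit(
                slope1=float(coef[1]), slope2=float(coef[1] + coef[2]),
                breakpoint=float(tb), breakpoint_index=k,
                intercept=float(coef[0]), sse=sse,
            )
    assert best is not None
    return best


def fit_fusion(trace: KineticTrace) -> FitResult:
    """Fit (Gamma, a) of the coalescence model (r/R)^2 = a (1 - exp(-Gamma t)).

    Bounds: Gamma > 0, 0 < a <= 1.2 (the headroom above 1 absorbs noise).
    The result is tagged 'complete' when a >= 0.9 and 'arrested'
    otherwise (``extra['classification']``).  A trace with no signal is
    flagged as failed.
    """
    if len(trace) < 4:
        raise ValueError("need at least 4 points")
    t, y = trace.t, trace.y

    def flagged(msg):
        return FitResult(
            params={"gamma": float("nan"), "amplitude": float("nan")},
            stderr={"gamma": float("nan"), "amplitude": float("nan")},
            window=(float(t[0]), float(t[-1])), residual_rms=float("nan"),
            converged=False, n_points=int(t.size), message=msg,
        )

    if np.allclose(y, 0.0):
        return flagged("trace carries no signal")

    def resid(theta):
        g, a = theta
        return a * (1.0 - np.exp(-g * t)) - y

    y_end = max(float(np.clip(y[-1], 1e-3, 1.2)), 1e-3)
    half = t[y > 0.5 * y_end]
    g0 = float(np.log(2.0) / half[0]) if half.size else 1.0 / t[-1]
    res = least_squares(resid, x0=[g0, y_end],
                        bounds=([1e-12, 1e-12], [np.inf, 1.2]))
    if not res.success:
        return flagged(f"optimizer failed: {res.message}")
    g, a = res.x
    se = stderr_from_jacobian(res.jac, res.fun)
    tag = "complete" if a >= COMPLETE_FUSION_AMPLITUDE else "arrested"
    return FitResult(
        params={"gamma": float(g), "amplitude": float(a)},
        stderr={"gamma": float(se[0]), "amplitude": float(se[1])},
        window=(float(t[0]), float(t[-1])),
        residual_rms=float(np.sqrt(np.mean(res.fun**2))),
        converged=True, n_points=int(t.size),
        extra={"classification": tag},
    )


def fit_fusion_scaling(pairs: Sequence[FusionPair], through_origin: bool = True,
                       units: str = "um/h") -> FitResult:
    """Surface-tension-to-viscosity ratio from the fusion-rate size scaling.

    The coalescence rate of two viscous droplets of radius R0 scales as
    Gamma ~ (sigma/eta) / R0, so 1/Gamma is regressed on R0 (through the
    origin by default, since the scaling law has no intercept) and
    sigma/eta = 1/slope.  A free-intercept variant is available for
    diagnostics.

    Parameters
    ----------
    pairs : sequence of FusionPair
        At least 3, spanning at least 2 distinct radii.
    through_origin : bool
    units : str
        Units of sigma/eta implied by the units of gamma and R0
        (um/h when gamma is 1/h and R0 um); recorded, never converted.

    Returns
    -------
    FitResult over ('sigma_over_eta', 'slope').
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 fusion pairs")
    r0 = np.array([p.R0 for p in pairs], dtype=float)
    gamma = np.array([p.gamma for p in pairs], dtype=float)
    if np.unique(r0).size < 2:
        raise ValueError("pairs must span at least 2 distinct radii")
    if np.any(gamma <= 0):
        raise ValueError("fusion rates must be positive")
    inv_gamma = 1.0 / gamma

    if through_origin:
        slope = float(r0 @ inv_gamma / (r0 @ r0))
        resid = inv_gamma - slope * r0
        dof = r0.size - 1
        se_slope = float(np.sqrt((resid @ resid) / dof / (r0 @ r0)))
        window = (float(r0.min()), float(r0.max()))
        n = r0.size
        rms = float(np.sqrt(np.mean(resid**2)))
    else:
        res = stats.linregress(r0, inv_gamma)
        slope, se_slope = float(res.slope), float(res.stderr)
        resid = inv_gamma - (res.intercept + slope * r0)
        window = (float(r0.min()), float(r0.max()))
        n = r0.size
        rms = float(np.sqrt(np.mean(resid**2)))
    sigma_over_eta = 1.0 / slope
    se_ratio = se_slope / slope**2  # delta method
    return FitResult(
        params={"sigma_over_eta": sigma_over_eta, "slope": slope},
        stderr={"sigma_over_eta": se_ratio, "slope": se_slope},
        window=window, residual_rms=rms, converged=True, n_points=n,
        extra={"units": units, "through_origin": through_origin},
    )


def fit_recoil(trace: KineticTrace) -> FitResult:
    """Initial recoil and relaxation rate of a post-ablation vertex trace.

    Model: f(t) = (r0 / k)(1 - exp(-k t)), with f the increase of vertex
    separation over the initial contact length (f(0) = 0 by
    construction), r0 = df/dt at t = 0 the initial recoil velocity, and
    k > 0 the relaxation rate.

    Returns
    -------
    FitResult over ('initial_recoil', 'k').  A flat trace returns an
    initial recoil of exactly 0 (k is then unidentifiable and NaN); a
    non-positive optimal k is flagged.
    """
    if len(trace) < 5:
        raise ValueError("need at least 5 points")
    t, y = trace.t, trace.y
    if np.allclose(y, 0.0):
        return FitResult(
            params={"initial_recoil": 0.0, "k": float("nan")},
            stderr={"initial_recoil": 0.0, "k": float("nan")},
            window=(float(t[0]), float(t[-1])), residual_rms=0.0,
            converged=True, n_points=int(t.size),
            message="flat trace: no recoil, relaxation rate unidentifiable",
        )

    def resid(theta):
        r0, k = theta
        return (r0 / k) * (1.0 - np.exp(-k * t)) - y

    # slope of the first two samples as r0 init; plateau sets r0/k
    r0_init = float((y[1] - y[0]) / (t[1] - t[0])) if t.size > 1 else 1.0
    plateau = float(np.max(np.abs(y)))
    k_init = abs(r0_init) / plateau if plateau > 0 else 1.0
    res = least_squares(resid, x0=[max(r0_init, 1e-9), max(k_init, 1e-9)],
                        bounds=([0.0, 1e-12], [np.inf, np.inf]))
    converged = bool(res.success and res.x[1] > 1e-10)
    se = stderr_from_jacobian(res.jac, res.fun)
    return FitResult(
        params={"initial_recoil": float(res.x[0]), "k": float(res.x[1])},
        stderr={"initial_recoil": float(se[0]), "k": float(se[1])},
        window=(float(t[0]), float(t[-1])),
        residual_rms=float(np.sqrt(np.mean(res.fun**2))),
        converged=converged, n_points=int(t.size),
        message="" if converged else "relaxation rate pinned at zero",
    )


def apical_response(trace: KineticTrace, t_probe: float = 3.0) -> float:
    """Relative apical-area change y(t_probe) - 1 of a normalized trace.

    The trace must start at 1 at t = 0 and cover ``t_probe``; the value at
    ``t_probe`` is linearly interpolated between the straddling samples.
    """
    if trace.t[0] > 0 or trace.t[-1] < t_probe:
        raise ValueError("trace must cover [0, t_probe]")
    return float(np.interp(t_probe, trace.t, trace.y) - 1.0)
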