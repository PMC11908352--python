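"""Fit-result container shared by every estimator in the package."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class FitResult:
    """Named parameter estimates with uncertainties and fit diagnostics.

    Attributes
    ----------
    params : dict
        Parameter name -> point estimate.
    stderr : dict
        Parameter name -> standard error from the Jacobian at the optimum
        (NaN when the curvature is degenerate).
    window : tuple
        ``(lo, hi)`` range of the independent variable actually fitted.
    residual_rms : float
        Root-mean-square residual, in the units of the fitted data.
    converged : bool
        False when the optimizer failed or a degenerate input was flagged;
        estimates are then best-effort and should not be trusted.
    n_points : int
        Number of data points inside the fit window.
    message : str
        Human-readable status (convergence diagnostics, active bounds...).
    extra : dict
        Estimator-specific diagnostics (e.g. classification tags).
    """

    params: dict[str, float]
    stderr: dict[str, float]
    window: tuple[float, float]
    residual_rms: float
    converged: bool
    n_points: int
    message: str = ""
    extra: dict[str, Any] = field(default_factory=dict)

    @property
    def bse(self) -> dict[str, float]:
        """Standard errors (statsmodels-style alias)."""
        return self.stderr

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def conf_int(self, nsigma: float = 1.96) -> dict[str, tuple[float, float]]:
        """Normal-approximation confidence intervals, +/- ``nsigma`` stderr."""
        return {
            k: (v - nsigma * self.stderr.get(k, math.nan),
                v + nsigma * self.stderr.get(k, math.nan))
            for k, v in self.params.items()
        }

    def summary(self) -> str:
        """Plain-text summary table of estimates and uncertainties."""
        lines = [
            f"{'parameter':<16}{'estimate':>14}{'std err':>14}",
            "-" * 44,
        ]
        for k, v in self.params.items():
            se = self.stderr.get(k, math.nan)
            lines.append(f"{k:<16}{v:>14.6g}{se:>14.3g}")
        lines.append("-" * 44)
        lines.append(
            f"n = {self.n_points}, window = ({self.window[0]:.4g}, {self.window[1]:.4g}), "
            f"residual RMS = {self.residual_rms:.4g}, converged = {self.converged}"
        )
        if self.message:
            lines.append(self.message)
        return "\n".join(lines)

    def to_dict(self) -> dict[str, Any]:
        return {
            "params": dict(self.params),
            "stderr": dict(self.stderr),
            "window": list(self.window),
            "residual_rms": self.residual_rms,
            "converged": self.converged,
            "n_points": self.n_points,
            "message": self.message,
            "extra": self.extra,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_json_default)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "FitResult":
        return cls(
            params=dict(d["params"]),
            stderr=dict(d["stderr"]),
            window=tuple(d["window"]),
            residual_rms=float(d["residual_rms"]),
            converged=bool(d["converged"]),
            n_points=int(d["n_points"]),
            message=d.get("message", ""),
            extra=d.get("extra", {}),
        )

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def stderr_from_jacobian(jac: np.ndarray, residuals: np.ndarray,
                         n_params: int | None = None) -> np.ndarray:
    """Standard errors of least-squares estimates from the Jacobian.

    Uses ``cov = s^2 (J^T J)^-1`` with ``s^2 = SSE / (n - p)``, inverted
    through the SVD *without* truncating small singular values: a nearly
    unidentifiable parameter direction must come back with a huge
    standard error, not a silently small one.
    """
    n = residuals.size
    p = n_params if n_params is not None else jac.shape[1]
    if n <= p:
        return np.full(jac.shape[1], np.nan)
    sse = float(residuals @ residuals)
    s2 = sse / (n - p)
    try:
        _, sing, vt = np.linalg.svd(jac, full_matrices=False)
    except np.linalg.LinAlgError:
        return np.full(jac.shape[1], np.nan)
    # floor only to avoid division overflow; keeps tiny singular values
    # honest (stderr -> very large) instead of dropping them
    floor = max(sing[0], 1.0) * 1e-150
    inv_s2 = 1.0 / np.maximum(sing, floor) ** 2
    var = np.einsum("ji,j,ji->i", vt, inv_s2, vt) * s2
    var[var < 0] = np.nan
    return np.sqrt(var)
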