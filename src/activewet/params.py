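"""Parameter bundles for the annular active-polar-fluid model.

The spreading monolayer is described by two composite dynamical
parameters rather than by the four underlying material constants:

``A``
    traction-to-viscosity ratio, units 1/(um h).  ``A * Lc**2`` is a
    velocity scale (um/h) set by the maximal traction stress.
``B``
    contractility-to-viscosity ratio, units 1/h.  ``B * R`` is the
    velocity scale of the contractile back-flow.

The geometry is an annulus: an outer spreading front at radius ``R``
and an inner unspread "solid core" of radius ``R1`` where the radial
flow vanishes.  ``Lc`` is the nematic length over which planar cell
polarity decays from the edge inward.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the annular polar-fluid velocity solution.

    Attributes
    ----------
    A : float
        Composite traction parameter, 1/(um h).
    B : float
        Composite contractility parameter, 1/h.
    Lc : float
        Nematic length, um.  Must be positive.
    R : float
        Outer (spreading-front) radius, um.  Must be positive.
    R1 : float
        Inner (solid-core) radius, um.  ``0 <= R1 < R``.
    """

    A: float
    B: float
    Lc: float
    R: float
    R1: float = 0.0

    def __post_init__(self) -> None:
        if not self.Lc > 0:
            raise ValueError(f"Lc must be positive, got {self.Lc}")
        if not self.R > 0:
            raise ValueError(f"R must be positive, got {self.R}")
        if not 0 <= self.R1 < self.R:
            raise ValueError(f"R1 must satisfy 0 <= R1 < R, got R1={self.R1}, R={self.R}")

    def rescaled(self, length: float = 1.0, time: float = 1.0) -> "ModelParams":
        """Return parameters after rescaling lengths by ``length`` and times by ``time``.

        ``A*Lc**2`` and ``B*R`` remain velocities in the new units, so the
        dimensionless shape of the solution is unchanged.
        """
        return replace(
            self,
            A=self.A / (length * time),
            B=self.B / time,
            Lc=self.Lc * length,
            R=self.R * length,
            R1=self.R1 * length,
        )


@dataclass(frozen=True)
class TractionFitParams:
    """Parameters of the radial traction profile Tr(r) = -T0 I1(r/Lc)/I1(R/Lc).

    Attributes
    ----------
    T0 : float
        Maximal traction stress at the fully polarized edge (Pa or kPa,
        whatever unit the profile carries).  Nonnegative.
    Lc : float
        Nematic length, um.
    R : float
        Monolayer radius, um.
    """

    T0: float
    Lc: float
    R: float

    def __post_init__(self) -> None:
        if self.T0 < 0:
            raise ValueError(f"T0 must be nonnegative, got {self.T0}")
        if not self.Lc > 0:
            raise ValueError(f"Lc must be positive, got {self.Lc}")
        if not self.R > 0:
            raise ValueError(f"R must be positive, got {self.R}")
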