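# Methods

This note documents the models, estimators, numerical choices and known
limitations of `activewet`.

## Annular active polar fluid model

**Assumptions.** The spreading monolayer is a thin, incompressible-in-plane
active polar fluid in the low-Reynolds (Stokes) regime. Polarity relaxes much
faster than the spreading timescale (adiabatic limit), is purely radial, and
obeys `Lc² ∇²p = p` with full edge polarization `p(R) = 1` and `p(0) = 0` by
symmetry. Hydrostatic contributions and the antisymmetric stress are
neglected. The central 3D aggregate is a rigid core: `v(R1) = 0`; the
spreading front is stress free: `σ_rr(R) = 0`.

**Identifiable parameters.** Velocimetry cannot separate the traction scale
`T₀`, viscosity `η`, thickness `h` and contractility `ζ` individually — only
the composites `A` (units 1/(µm·h), traction/viscosity) and `B = −ζ/η`
(units 1/h) enter the velocity profile. The package treats them as opaque
parameters throughout and makes no attempt to decompose them; `A Lc²` and
`B R` are the two velocity scales of the problem. Traction-force microscopy
separately measures `T₀` in physical stress units.

**Force balance and sign convention.** Dividing the stress divergence by
`2η` gives

```
v'' + v'/r − v/r² = −(B/2)[(p²)' + p²/r] − (A/2) p .
```

The sign of the `A` term is fixed by requiring outward flow (positive `v`
with its peak in the outer half of the annulus) for pure traction forcing
(`A > 0, B = 0`), which is the observed phenomenology of spreading
monolayers.

**Closed form.** The radial operator factorizes as
`L v = d/dr[(1/r) d(r v)/dr]`, and two Bessel identities give exact
particular solutions:

- `∫ I₁(x)²/x dx = (I₀² − I₁²)/2`  →  `v_B = −(B Lc/4) I₀(x)I₁(x)/I₁(X)²`,
- `L[I₁(r/Lc)] = I₁(r/Lc)/Lc²`      →  `v_A = −(A Lc²/2) I₁(x)/I₁(X)`,

with `x = r/Lc`, `X = R/Lc`. The homogeneous part `c₁ r + c₂/r` is fixed by
the two boundary conditions through a 2×2 linear solve (Cramer form); on the
full disk (`R1 = 0`) regularity forces `c₂ = 0`. The solution is exactly
linear in `(A, B)` — the fitting code exploits this.

**Numerics.** All Bessel ratios use exponentially scaled `scipy.special.ive`
so `R/Lc` up to several hundred cannot overflow. The independent oracle is a
`solve_bvp` collocation solution of the same boundary-value problem
(tolerance 10⁻¹⁰); for the disk the inner boundary moves to `10⁻⁶ R` with
the regularity condition `a v'(a) = v(a)`, accurate to `O((a/R)²)`.
Closed form and collocation agree to better than 10⁻⁶ sup-norm relative over
`Lc/R ∈ [0.05, 5]`, `R1/R ∈ [0, 0.9]`.

## Profile fitting

**Velocity profiles.** `R` is held fixed (the segmentation boundary);
`(A, B, Lc, R1)` are free with bounds `A, B ≥ 0`, `Lc > 0`, `0 ≤ R1 < R`.
The fit window runs from the first bin to 1.07× the position of the profile
maximum (configurable), trimming the outermost bins whose azimuthal averages
are corrupted by the ragged front. Initialization profiles the exact
`(A, B)` linearity: a grid over `(Lc, R1)` (12 log-spaced `Lc/R` values ×
10 core radii including the data-driven guess — the first radius where the
smoothed profile exceeds 10% of its maximum) is solved by nonnegative least
squares, and the best node seeds a bounded trust-region polish
(`scipy.optimize.least_squares`); five deterministic multistarts are the
fallback. Inside a trial core (`r < R1`) the model velocity is zero.

**Uncertainties.** Standard errors come from the Jacobian at the optimum,
`cov = s²(JᵀJ)⁻¹` with `s² = SSE/(n − p)`, inverted through the SVD
*without* truncating small singular values, so nearly unidentifiable
directions report honestly large errors. Limitation: at 5% profile noise the
`(A, B, Lc)` likelihood surface is a long curved valley; in roughly 5% of
noise realizations the global minimum sits at small `Lc`/large `B`, where a
local linearized interval cannot reach the generating values. Monte-Carlo
calibration shows ≈94–97% coverage of `±3 stderr` for `Lc` (≥98% for the
other parameters); a profile-likelihood interval would be better calibrated
but is not what the estimator reports.

**Traction profiles.** The monolayer radius is set to the bin of maximum
traction magnitude and the outer region discarded (poorly attached
protrusions and long-range substrate deformation corrupt it); `(T₀, Lc)` are
then fitted with `T₀ ≥ 0`. The fit is sign-agnostic (inward-negative radial
components or magnitudes give identical estimates). Because the fitted `R`
sits up to one bin inside the true edge, `T₀` carries a discretization bias
of order `exp(−Δbin/Lc) − 1`; at the default synthetic bead density this is
≈4%.

## PIV

Interrogation windows (power-of-two, ≥16 px; paper-matched defaults 32 px /
50% overlap) are mean-subtracted, Hann-tapered, and correlated by FFT; the
correlation is divided by the taper's autocorrelation envelope so the taper
does not bias the peak. The peak (searched within ±window/4) is refined by a
9-point log-Gaussian paraboloid fit, falling back to per-axis 3-point
Gaussian/parabolic interpolation. A multi-pass integer window offset
re-correlates until only a subpixel remainder is left, which removes the
loss-of-pairs bias that grows with displacement. Windows below the
valid-pixel coverage threshold or with zero intensity variance are masked,
not raised. An optional (default-on) normalized-median outlier filter
replaces vectors farther than `3·(MAD + floor)` from their 3×3 neighbor
median. Measured accuracy on the speckle fixtures: integer shifts to
~10⁻¹⁵ px, subpixel shifts to ≤0.02 px worst case. No iterative window
deformation is implemented; strongly sheared flows beyond ±window/4 per
frame are out of reach.

## Traction-force microscopy

The substrate is a semi-infinite isotropic elastic half-space (default
`E = 15 kPa`, `ν = 0.5`, the soft-PDMS gel values). The Fourier-space
Boussinesq kernel

```
K(q) = 2(1+ν)/(E q³) [[(1−ν)q² + ν q_y², −ν q_x q_y],
                      [−ν q_x q_y, (1−ν)q² + ν q_x²]]
```

maps traction to surface displacement; the `q = 0` mode is undefined on a
half-space and set to zero (inputs should be near force-free). FTTC solves
`T = (KᵀK + λ²I)⁻¹Kᵀu` mode by mode; `λ = 0` is the exact inverse, and
forward/inverse are mutually inverse to <10⁻⁸ on smooth tractions. Scattered
bead displacements are gridded by Delaunay-linear interpolation (outside-hull
nodes masked, zero-filled before the FFT). An optional Hann taper +
mean subtraction is available for non-periodic data but is off by default so
the operator pair stays exactly inverse.

**Regularization.** `λ` is either user-supplied or selected at the L-curve
corner (maximum curvature of log residual norm vs log solution norm, after
discarding the under-regularized plateau where the residual sits at the
noise floor). Limitation, measured on Gaussian-correlated synthetic
tractions at 5% displacement noise: the corner (and GCV, cross-checked)
systematically selects `λ` about 2× below the MSE-optimal value, giving
20–35% RMS traction error where the oracle `λ` achieves 11–15% — consistent
with published FTTC benchmarks. Reconstructions near the optimum remain
>5× better than the unregularized inversion.

## Kinetics

All linear fits are ordinary least squares (`scipy.stats.linregress`; the
through-origin fusion-scaling fit uses the closed-form origin-constrained
estimator, since `Γ ≃ σ/(ηR₀)` has no intercept — a free-intercept variant
exists for diagnostics). Nonlinear fits are bounded least squares with
Jacobian standard errors. Notable contracts:

- spreading rate: frames gated at a 20% excess over the initial projected
  area and `t ≤ 24 h` before the linear fit, ≥5 gated points required;
- two-segment coverage regression: continuous two-piece line, exhaustive
  search over interior sample breakpoints, ties resolved to the earliest
  breakpoint within a `10⁻¹⁰`-relative SSE tolerance;
- fusion: `(r/R)² = a(1 − e^(−Γt))` with `Γ > 0`, `0 < a ≤ 1.2` (headroom
  above 1 absorbs noise); `a ≥ 0.9` is tagged "complete", below it
  "arrested" coalescence;
- recoil: `f(t) = (r₀/k)(1 − e^(−kt))`; a flat trace returns exactly zero
  initial recoil with `k` marked unidentifiable;
- `σ/η` is reported in the units implied by its inputs (µm/h for `Γ` in 1/h
  and `R₀` in µm) and recorded as metadata, never converted implicitly.

## Synthetic data

Generators are deterministic given a single seed and return machine-readable
truth records. They emulate: model-driven radial flows on a growing/melting
annulus with additive isotropic Gaussian node noise (default 5% of the peak
speed); Gaussian speckle pairs (spot σ 1.5 px, continuous positions) for
PIV; bead tables from the Bessel traction pushed through the Boussinesq
forward operator (defaults ~1 bead/µm² over a 2.25 R field, 0.05 µm
positional noise — dense enough to resolve the traction edge); exponential
fusion traces on the 1/8/24/48/72 h imaging grid and recoil/area/melting
traces (3% noise); growing-disk masks; and a spectrally synthesized Gaussian
field with exponential spatial correlation for the correlation-length round
trip.

What they do **not** emulate: phase-contrast texture and segmentation error,
bead tracking failures, drift, uneven illumination, temporal correlation of
noise, non-radial flows, or finite-thickness substrate effects. Passing
recovery tests therefore demonstrate estimator correctness under the stated
noise model, not robustness to every artifact of real microscopy.

## Problem sizes

Defaults keep the full suite and the benchmark script fast on a single CPU:
48² velocity grids over ≤10 frames, 256² speckle images, 128²–256² FTTC
grids, 200 Monte-Carlo replicates for the calibration check. All are
package-level defaults chosen to make the statistical checks meaningful at
interactive run times; every generator scales up by argument.
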