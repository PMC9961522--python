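# Methods

## Reconstruction model

Phase-based Helmholtz-EPT assumes locally homogeneous electric properties, so
the Helmholtz equation for the rotating transmit field B1+ reduces, after
separating magnitude and phase and discarding the magnitude term, to
`σ ≈ ∇²φ± / (2 ω μ₀)` with φ± the transceive phase and ω the angular Larmor
frequency (2π·128 MHz at 3 T; μ₀ = 4π×10⁻⁷ H/m exactly). The complete variant
keeps the magnitude term, `σ = ∇²φ+/(ωμ₀) + 2∇|B1+|·∇φ+/(ωμ₀|B1+|)` with
φ+ = φ±/2. The relative magnitude gradient is computed as the
Savitzky–Golay gradient of log|B1+| — a numerically convenient form that is
exact for log-linear sensitivity profiles and avoids dividing two noisy
derivative estimates. Uncertainty propagation is implemented only for the
phase-based method, which is linear in the data; the complete method's
magnitude dependence makes it nonlinear and it is reconstructed without a
covariance.

No phase unwrapping is attempted. A detector raises an error when two
neighboring voxels inside the analysis region differ by more than π; phantom
phases are far from wrapping, and silently unwrapping would mask data
problems.

## Savitzky–Golay differential kernels

The Laplacian is estimated per voxel by an unweighted least-squares fit of a
quadratic polynomial on a kernel of integer offsets — a cross (6n+1 points),
voxelized sphere (all offsets with ‖o‖ ≤ n) or cube ((2n+1)³ points) — and
evaluating 2(a₂₀₀+a₀₂₀+a₀₀₂) analytically; the gradient comes from the same
fit. "Robust" here means the noise robustness of local polynomial fitting;
no outlier reweighting is applied (an iteratively reweighted variant would
change no interface and is left to future work).

The polynomial basis is chosen by support geometry: the full 10-term
quadratic basis wherever the support determines it, and the reduced 7-term
basis (no mixed monomials) on axis-only supports — the cross at any n and
the sphere at n=1 — where mixed monomials vanish identically and would make
the design matrix rank-deficient. On the 7-point axis support the fit is
exactly determined and reproduces the classical finite-difference Laplacian.
The design matrix is evaluated in voxel units and rescaled afterwards
(1/h² for the Laplacian weights, 1/h for the gradient) for conditioning.
By construction the weights annihilate constants, are symmetric under offset
negation, and return the exact Laplacian/gradient of any quadratic field;
the reconstruction of a synthetically quadratic phase is therefore exact to
machine precision, which the test suite uses as its primary oracle.

Voxel centers sit at (i+0.5)·h from the grid corner; flat indices are
Fortran-ordered (x fastest, z slowest). A voxel belongs to the spherical
analysis region when its *center* lies within the radius. With a 3 cm radius
on a 2 mm grid, and the sphere centered at the grid center of an even-sized
grid (a voxel corner), this gives Np = 14328 members. Conventions that
require the whole voxel inside the sphere give counts closer to 11,500; the
package logs the exact count and convention on every mask construction and
treats published approximate counts as convention-dependent. Conductivity is
only reconstructed where the entire kernel lies inside the region (no
padding or extrapolation), so the target count Ns strictly decreases as the
kernel grows: 12064 (cross n=1) down to 1400 (cube n=5) on the mask above.

## Covariance estimation and propagation

With K scans against ~10⁴ voxels the experimental covariance of the mean,
`S = 1/(K(K−1)) Σₖ (pₖ−p̄)(pₖ−p̄)ᵀ`, has rank K−1 and wildly unstable
off-diagonals. The estimate used throughout is the James–Stein-type
shrinkage `Σ = λS + (1−λ)diag(S)`, which preserves the empirical variances
and damps the correlations. λ follows the analytic Schäfer–Strimmer
minimizer computed on sample correlations: λ = 1 − λ*, with
λ* = Σ_{i≠j} Vâr(r̂ᵢⱼ) / Σ_{i≠j} r̂ᵢⱼ², clipped to [0,1]. Both sums are
evaluated through K×K Gram matrices of the standardized deviations, so the
cost is O(N K²) and no N×N matrix is formed; because correlations are
scale-free the 1/(K(K−1)) normalization cancels. When every off-diagonal
sample correlation is zero the estimate collapses onto the diagonal (λ = 0);
when all variances are numerically zero (identical scans) the covariance is
zero and shrinkage is skipped. Estimating λ requires K ≥ 3; with exactly two
scans the raw experimental matrix is used.

Before covariance estimation under repeatability conditions, each phase map
is translated to zero mean over the analysis sphere. Constant offsets carry
no conductivity information (the Laplacian annihilates them) but would
otherwise appear as a spurious, perfectly correlated rank-one component.

Propagation through the linear reconstruction keeps the factored structure
exactly: `Σ(s) = (√λ A X)(√λ A X)ᵀ + (1−λ) A diag A ᵀ`, an Ns×K factor plus
a sparse symmetric matrix. The container exposes `diagonal()`,
`quadratic_form(v)` and `solve(rhs)`. Solves use conjugate gradient on the
combined matvec with a Jacobi preconditioner (relative residual 10⁻¹⁰);
profiling at production size (Ns ≈ 7500, sphere n=3) showed CG converging in
~500 iterations (~2 s) where a sparse LU of the 4.6M-nonzero sparse part
plus a rank-K Woodbury update took ~12 s, so CG is primary and LU/Woodbury
the fallback. At λ = 1 the matrix has rank K−1 and solves raise an error.
Dense assembly exists only for tests on grids ≤ 16³, where diagonal,
quadratic forms and solves of the factored path are verified to 10⁻⁸.

Under reproducibility conditions the phantom moves between scans, so phase
maps are not averaged; each scan is reconstructed on an analysis sphere
re-centered at that scan's phantom position (positions are snapped to whole
voxels, making all spheres exact lattice translates, so maps compare
matching regions of the phantom), and the same shrinkage estimator is
applied directly to the K conductivity maps.

## Spatial averages

The plain average s̄ carries `u(s̄) = √(1ᵀΣ(s)1)/Ns` — the full double sum,
so positive correlations properly inflate the uncertainty. The
precision-weighted average s̄w = (1ᵀΣ⁻¹s)/(1ᵀΣ⁻¹1) with
u(s̄w) = (1ᵀΣ⁻¹1)^{-1/2} is the generalized least-squares estimate of the
common value of a homogeneous region; by Cauchy–Schwarz u(s̄w) ≤ u(s̄)
always, with equality at Σ = I, and the package asserts this on every run.
In the exact zero-covariance limit (noise-free synthetic data) the weighted
average is defined as the plain mean with zero uncertainty. Boxplot
quantiles use linear interpolation between order statistics (numpy's
default, "type 7"); spatial dispersion is the ddof=1 standard deviation of
the map. Relative uncertainties are reported in percent to 3 decimals.

## Synthetic phantom generator

The generator's job is to produce scan sets with the statistical structure
the analysis assumes, with a known truth. The transceive phase is
constructed as φ± = (ωμ₀σ/3)|r−c|² plus optional zero-Laplacian harmonic
terms, so the discrete reconstruction is exact by construction and parameter
recovery is a valid oracle — it deliberately is *not* a solution of
Maxwell's equations for the coil/phantom geometry. On top of the truth:

* an **artifact field** — Gaussian white noise smoothed with an isotropic
  Gaussian and rescaled — fixed across repetitions of an unmoved phantom and
  redrawn at every repositioning. Default amplitude 0.02 rad (s.d.),
  correlation length 1 cm: chosen once so that, qualitatively, the
  repeatability uncertainty sits well below the spatial dispersion while the
  reproducibility uncertainty tracks it, the contrast observed on real
  phantom data. The real artifacts' spatial scale is not known
  quantitatively; these are order-of-magnitude stand-ins.
* **i.i.d. Gaussian phase noise**, fresh per scan, default s.d. 0.01 rad
  (magnitude SNR ≈ 100, typical for a 3D SSFP phantom scan at 2 mm).

Defaults mirror the targeted experiment: 2 mm isotropic grid (48³ for
repeatability; large enough to hold the repositioning ring for
reproducibility), 128 MHz, K=25 repetitions, 8 reproductions on a ring with
successive centers 6 cm apart, conductivity 560 mS/m (the 64 mM NaCl value
at 17 °C from the linear 550→570 mS/m law over 16–18 °C, which the package
implements in place of the full seawater-conductivity equations). One master
seed drives per-scan artifact and noise streams through spawned
`SeedSequence`s, so studies are bit-reproducible.

What the synthetic studies do **not** contain: B1-related systematic errors
of the phase-based approximation (the synthetic truth is exactly quadratic),
coil-combination and sequence physics, B0 drift, motion of the saline, or
position-dependent |B1+| distributions. Consequently, passing tests
demonstrate the correctness and internal calibration of the estimator chain
— not the accuracy of phase-based EPT on real data, where the phase-based
bias (order +5 % on real phantom scans) dominates plain averages.

## Calibration scope of the coverage check

The 2σ coverage of s̄w against the programmed conductivity is asserted over
50 seeded replicates with the default noise and **no artifact field**. This
is deliberate: the repeatability covariance is estimated from scan-to-scan
variability and is structurally blind to any error that repeats identically
in every scan — that blindness is the central repeatability/reproducibility
contrast, checked separately. With the artifact on, the artifact's random
(per-seed) offset of the regional average (~±60 mS/m) exceeds u(s̄w)
(~0.2 mS/m) by orders of magnitude, and no covariance estimated under
repeatability conditions could cover it. Coverage is therefore a calibration
statement about the error sources the covariance models. Measured: the
seed-to-seed dispersion of s̄w (0.21 mS/m) matches u(s̄w) (0.216 mS/m), and
coverage is 94 % at n=50.

## Problem sizes and tolerances used by the tests

Unit tests run on 24³ grids with a 1.2 cm sphere (seconds). The integrated
checks use: the production 48³/3 cm geometry for exactness (all 15 kernels,
10⁻⁸ relative), a 12³ grid with 2×2000 scans for the Monte-Carlo variance
oracle (agreement within 10 % and 3 MC standard errors on the mean ratio; a
per-voxel 3σ bound over ~10³ voxels would fail by chance alone), 16³ for
dense-vs-factored equivalence (10⁻⁸), 50 replicates of the full K=25
repeatability study for coverage, and a 112³ grid for the 8-position
reproducibility ring. The whole suite completes in a few minutes on one CPU.

## Known limitations

* Permittivity (the real part of the complete Helmholtz inversion) is not
  estimated; on clinical field strengths its SNR is too low to be useful.
* No boundary-aware reconstruction: the operator refuses voxels whose kernel
  crosses the analysis-region boundary rather than padding.
* Uncertainty propagation covers the phase-based method only.
* The λ printed by the pipeline is the analytic correlation-scale estimator;
  published analyses using other members of the shrinkage family (e.g.
  shrinking variances as well) will differ in λ while preserving the
  diagonal, so region-level uncertainties are comparable but not identical.
* Anisotropic voxels, 2D kernels and DICOM ingestion are unsupported.
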