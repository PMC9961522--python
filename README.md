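# eptuq — uncertainty assessment for Helmholtz-EPT conductivity phantom studies

Electric properties tomography (EPT) turns routine MRI acquisitions into
quantitative maps of tissue electric conductivity at the Larmor frequency.
Before such maps can be compared across scans or sites, the measurement
uncertainty of the reconstruction must be quantified. `eptuq` implements the
complete uncertainty-assessment chain for phase-based Helmholtz-EPT applied
to a homogeneous phantom, together with a synthetic phantom generator that
reproduces the statistical structure of repeated ("repeatability") and
repositioned ("reproducibility") scan sets. It is aimed at quantitative-MRI
researchers and metrologists who need voxelwise and region-level conductivity
uncertainties, not just conductivity values.

## Model

Phase-based Helmholtz-EPT estimates the conductivity from the transceive
phase φ± of a standard sequence:

    σ ≈ ∇²φ± / (2 ω μ₀),        ω = 2π·128 MHz at 3 T,

with the complete variant adding the transmit-sensitivity correction
`2 ∇|B1+|·∇φ+ / (ω μ₀ |B1+|)`, φ+ = φ±/2. The Laplacian (and gradient) are
discretized with a 3D Savitzky–Golay filter: a local least-squares paraboloid
fit on a cross-, sphere- or cube-shaped kernel of half-width n (bounding cube
edge 2n+1 voxels), exact on quadratic fields. Restricted to a spherical
analysis region of radius 3 cm, the filter becomes a sparse operator `A` with
`s = A p` mapping the `Np` phase samples to `Ns` conductivity voxels.

The covariance of the mean phase over K repetitions (or of the mean
conductivity over K reproductions) is estimated with James–Stein shrinkage
towards its diagonal,

    Σ ≈ λ S + (1 − λ) diag(S),

with λ chosen analytically on the correlation scale (Schäfer–Strimmer), and
propagated through the linear reconstruction, `Σ(s) = A Σ(p) Aᵀ`, in
low-rank-plus-sparse form (never a dense Np×Np matrix). Region summaries are
the plain spatial average with `u(s̄) = √(1ᵀ Σ(s) 1) / Ns` and the
precision-weighted (generalized least-squares) average

    s̄w = (1ᵀ Σ(s)⁻¹ s) / (1ᵀ Σ(s)⁻¹ 1),   u(s̄w) = (1ᵀ Σ(s)⁻¹ 1)^(−1/2),

which is never less precise than the plain average.

## Worked example

```python
import eptuq as e

acq = e.AcquisitionSpec(rng_seed=7)          # 48^3 grid, 2 mm, 25 repetitions
phantom = e.PhantomSpec()                    # 560 mS/m saline cylinder
study = e.simulate_repetitions(acq, phantom)
summary = e.run_repeatability(study, kernel_shape="sphere", n=3)

a = summary.average
print(f"Np = {summary.n_sources}, Ns = {summary.n_targets}, lambda = {summary.lam:.3f}")
print(f"s_bar   = {1e3*a.s_bar:8.3f} mS/m  (ur = {a.ur_s_bar:.3f} %)")
print(f"s_bar_w = {1e3*a.s_bar_w:8.3f} mS/m  (ur = {a.ur_s_bar_w:.3f} %)")
rec = summary.dispersion_vs_uncertainty
print(f"voxelwise uncertainty = {1e3*rec['mean_voxel_uncertainty']:.1f} mS/m, "
      f"spatial dispersion = {1e3*rec['spatial_sd']:.1f} mS/m "
      f"(ratio {rec['uncertainty_to_dispersion_ratio']:.2f})")
```

prints

```
Np = 14328, Ns = 7544, lambda = 0.042
s_bar   =  614.200 mS/m  (ur = 0.077 %)
s_bar_w =  618.283 mS/m  (ur = 0.035 %)
voxelwise uncertainty = 52.1 mS/m, spatial dispersion = 113.1 mS/m (ratio 0.46)
```

The simulated study carries a smooth artifact field that is identical in all
25 repetitions: the mean map's spatial dispersion (113 mS/m) is therefore far
larger than the propagated repeatability uncertainty (52 mS/m) — repeated
averaging cannot remove an error that repeats. The weighted average is more
precise than the plain one (0.035 % vs 0.077 %), and both are offset from the
programmed 560 mS/m by this seed's artifact draw. Rerunning with
`simulate_reproductions` (fresh artifact per phantom position) makes the
voxelwise uncertainty track the dispersion instead.

The same pipeline is scriptable from the shell:

```
eptuq simulate --config cfg.yaml --out scans/
eptuq run --config cfg.yaml --out results/     # spatial_averages.csv + report.json
```

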