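# Methods

This note documents the models implemented in `ramanmix`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Signal model and estimators

All three estimators share the linear mixture picture: a measured Raman
spectrum `m ∈ R^L` on a fixed wavenumber axis is a weighted sum of
compound spectra plus noise. They differ in how much spectral
variability they admit.

**LS-qP.** The design matrix holds the K reference spectra and the q+1
basis polynomials of a q-th order polynomial in the wavenumber (default
q = 3). The weights are the minimum-norm least-squares solution via the
Moore–Penrose pseudoinverse with a relative singular-value cutoff of
1e-12. The polynomial block is a Chebyshev basis on the axis rescaled
affinely to [−1, 1]: only the spanned polynomial space matters to the
fit, and raw powers of wavenumbers ~10³ would be catastrophically
ill-conditioned. Duplicate or collinear columns are flagged
(`collinear`) but the fit proceeds — the pseudoinverse handles rank
deficiency. Negative weights are reported as-is; clipping would destroy
the sign information that distinguishes "absent" from "anti-correlated
residual structure".

**PCA calibration models.** Each compound's calibration library (N
replicate spectra) yields the mean S̄, the orthonormal principal
components Z_p of the mean-centred rows, and eigenvalues λ_p equal to
the sample variance (denominator N−1) of the projections onto Z_p.
Eigenvalues below 1e-12 × the largest (or below an absolute
floating-point floor that catches the dust left by mean subtraction of
identical spectra) count as zero; the model truncates to that numerical
rank and flags `truncated`. Component signs are fixed by making each
component's largest-magnitude element positive so fits are
deterministic. No normalisation (area, max) is applied to spectra before
PCA, and none is exposed: the estimators interpret weights as multiples
of the reference as measured.

**HLA.** The calibration vector is b = r / (r·S_A), where r is S_A minus
its projections onto the background components. Because S_A − r lies in
the component span, r·S_A = r·r, so this normalisation is identical to
dividing by r·r; it makes b·S_A = 1, so b·(m − S̄_bg) reads the weight
out directly and is exact on noiseless mixtures. The mean background is
subtracted before the dot product because the mean is not inside the
variation span that b annihilates. If r·S_A ≤ 1e-12 ‖S_A‖² the analyte
is numerically inside the background span and calibration raises a
degeneracy error. HLA itself produces no fitted spectrum; for
Durbin–Watson diagnostics the package reconstructs one as
ŵ·S_A + S̄_bg + (projection of the remainder onto the background span),
i.e. the residual is the part of the measurement neither the analyte
reference nor the background model can explain. This reconstruction is a
package choice — the estimator's weight does not depend on it.

**HLP.** The measured spectrum is x = Σ_k w_k (S̄_k + Σ_p c_pk Z_pk):
every reference flexes inside its own PCA model, and the flex
coefficients are penalized through the eigenvalues,

J(W, C) = ‖m − x‖² + β Σ c_pk²/λ_pk,  β = σ².

This is the MAP estimate under i.i.d. Gaussian measurement noise of
standard deviation σ and independent priors c_pk ~ N(0, λ_pk): the
eigenvalue-scaled prior is exactly how the calibration set's observed
variance constrains each mode, so no extra machinery is needed to couple
C to λ. σ is a single scalar (no wavelength-dependent weighting); it is
estimated from replicate measurements of a static target as the root of
the mean per-wavelength sample variance. `beta_override` exposes β
directly for sensitivity analyses and for the limiting checks below.

The cost is minimised by block-coordinate descent, zero-initialised:

1. **W-step** — with C fixed, form the L×K matrix of effective
   references S̄_k + Σ_p c_pk Z_pk and solve for W by minimum-norm
   pseudoinverse. (From the zero start this first step is plain CLS on
   the means; starting with the C-step instead would face an all-zero
   design.)
2. **C-step** — with W fixed, Q = m − Σ w_k S̄_k, the design column for
   (p,k) is w_k Z_pk, and C = (AᵀA + Γ)⁻¹AᵀQ with Γ = diag(β/λ_pk), a
   standard Tikhonov-regularised solve. If all weights are zero the step
   is skipped (zero design).

Each half-step minimises J exactly over its block, so the recorded cost
trace is nonincreasing — this is asserted in the test suite on every
study trial. Iteration stops when
max_k |w_k⁽ⁿ⁾ − w_k⁽ⁿ⁻¹⁾| / max(|w_k⁽ⁿ⁾|, 1e-12) < tol (default 1e-8)
or after max_iter = 500 iterations; on the default synthetic study
convergence typically takes tens of iterations. Components with zero
eigenvalue are excluded (the infinite-penalty limit pins their
coefficients to zero). Per-compound component counts may differ; the
default is 5 everywhere because estimates are insensitive to the count
once it exceeds three or four. Limiting behaviour, used as correctness
checks: with β → ∞ or with rank-zero calibration models HLP reduces
exactly to CLS on the mean spectra; with β → 0 and components spanning
the perturbation, noiseless perturbed mixtures are fitted to zero
residual.

K is general in the implementation; the shipped studies and tests
exercise K = 2 (one analyte, one background).

## Evaluation statistics

The Durbin–Watson statistic DW = Σ(e_i − e_{i−1})²/Σe_i², with the
residual ordered by ascending wavenumber, delegates to statsmodels. It
is undefined (raises) for all-zero residuals, including residuals whose
squares underflow. Fractional error is signed, (ĉ − c)/c; study
summaries report its mean and sample standard deviation (denominator
n−1) per method and weight level, plus the mean absolute value. DW
histograms share bin edges over [0, 4] across methods so they
superimpose.

## Synthetic data generator

Each synthetic spectrum is Σ peaks A_i(1+a_i)·G(x; c_i+s_i, w_i) + bump
+ noise, with a_i ~ N(0, amplitude_jitter), s_i ~ N(0, shift_jitter),
the bump a broad Gaussian with per-spectrum amplitude ~ N(A_b, σ_b), and
i.i.d. Gaussian noise. Defaults, chosen once as representative of SERS
nanoparticle / paraffin measurements:

| parameter | default | why |
|---|---|---|
| axis | 400–1800 cm⁻¹, L = 700 | typical fingerprint-region scan |
| analyte peaks | 8 narrow bands, widths 8–13 cm⁻¹ | reporter-dye-like signature |
| background peaks | 5 bands, widths 14–22 cm⁻¹ | paraffin-like narrow bands (~1063, 1296, 1441 cm⁻¹); narrow enough that their variation defeats a cubic baseline, which is the regime these methods target |
| baseline bump | centre 1700, width 80 cm⁻¹, amplitude 0.5 ± 0.2 | the strongly variable broad feature in the 1600–1800 region |
| amplitude_jitter | 0.05 | few-percent band-intensity drift |
| shift_jitter | 1 cm⁻¹ | sub-resolution peak wander |
| noise_sigma | 0.01 | SNR ≈ 100 for unit-height peaks, typical of 1 s acquisitions |

What the generator does **not** emulate: Poisson (shot-noise) statistics,
cosmic-ray spikes, detector baseline drift correlated across wavenumber,
autofluorescence decay, and the heavy-tailed outlier subpopulation seen
in real raster scans. Passing studies on this generator therefore
demonstrate the estimators' relative robustness to amplitude/position/
baseline variability under Gaussian noise; they do not certify
performance on real instrument data.

## Factorial study

The study forms m = v·analyte_i + background_j for every weight v in the
halving sequence 2⁰…2⁻¹³ (background unweighted) and every (i, j) pair,
and recovers v with each method calibrated leave-one-out: the analyte
model excludes spectrum i, the background model excludes spectrum j, so
an analysed spectrum never informs its own calibration. Leave-one-out
models are cached per excluded index (N_a + N_b PCA fits rather than
N_a × N_b). Weights become concentrations through the reference
concentration (default 0.8 nM, the stock concentration convention used
throughout). The full 14 × 106 × 476 = 706,384-combination grid is
supported; tests and the quickstart run a seeded subsample (10 analyte ×
20 background spectra, 2,800 combinations) so a study completes in well
under a minute on one CPU — the subsample size is a deliberate
desk-scale default, and the `subsample` knob lifts it.

## Numerical and design choices

* Pseudoinverse rank cutoff 1e-12 (relative) throughout.
* Axes must match exactly between spectra and models; resampling is
  always explicit (`resample`, linear interpolation, no extrapolation).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; studies and generated libraries are
  bit-reproducible.
* Serialized artifacts are plain text: libraries as delimited matrices,
  models/fits as JSON key–value trees, study outputs as CSV tables with
  a JSON run manifest.
* The statsmodels-style Model/Results shape was chosen because every
  estimator is "data in, fitted parameters + uncertainty diagnostics
  out"; the functional layer (`cls_fit`, `hla_calibrate`/`hla_estimate`,
  `hlp_fit`) remains public for scripting and for the study driver.

## Limitations

* Gaussian noise only; a Poisson likelihood would suit photon-counting
  detectors better at very low signal.
* σ is scalar across wavenumber.
* Multiplexed unmixing (K > 2) is implemented but not validated by the
  shipped studies.
* HLA's fitted spectrum (hence its DW) rests on the reconstruction
  convention described above.
* PCA models are linear; strongly nonlinear variation (large peak
  shifts) is only captured to first order, which is precisely the regime
  where HLP's eigenvalue constraint matters most.
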