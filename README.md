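# ramanmix

Spectral unmixing for Raman spectroscopy when the reference signatures are
not constant. The target application is quantifying Raman-enhanced
nanoparticle reporters (e.g. SERS gold–silica particles) in front of a
variable background such as paraffin or tissue, where both the analyte
spectrum and the background spectrum change from measurement to
measurement — peak amplitudes drift, peaks shift slightly, and broad
baseline features come and go.

## The models

A measured spectrum `m` (length `L`, intensities over a wavenumber axis)
is modelled as a weighted sum of reference spectra. Three estimators of
the analyte weight `w` are provided, all as statsmodels-style model
objects (`fit()` returns a Results object with `summary()`):

**Classical least squares with polynomial background (LS-qP).**
`m ≈ S W`, where the columns of `S` are the reference spectra plus the
`q+1` basis polynomials of a `q`-th order polynomial (default `q = 3`,
LS-3P); `W = S⁺ m` via the Moore–Penrose pseudoinverse. Fast, but blind
to any background variation a smooth curve cannot absorb.

**Hybrid linear analysis (HLA).** A calibration vector
`b = r / (r·S_A)` is built from the residual `r` of the analyte
reference `S_A` after projecting out the principal components `V_p` of a
background calibration set; the weight is the dot product
`w = b·(m − S̄_bg)`. Immune to every background variation mode inside the
component span, but models no variability in the analyte itself and
ignores the PCA eigenvalues.

**Hybrid least squares / PCA (HLP).** Each reference spectrum flexes
along its own calibration set's principal components,

    x = Σ_k w_k ( S̄_k + Σ_p c_pk Z_pk ),

and the flex is penalized by the eigenvalues λ_pk (the observed variance
of each mode). Estimation minimises the penalized least-squares cost

    J(W, C) = ‖m − x‖² + β Σ_{k,p} c_pk² / λ_pk ,   β = σ²,

(the maximum-a-posteriori estimate under Gaussian noise of standard
deviation σ and priors c_pk ~ N(0, λ_pk)), by alternating a pseudoinverse
solve for `W` with a Tikhonov-regularised solve for `C` from a zero
initial guess. The cost trace is guaranteed nonincreasing.

Weights convert to concentrations as `ĉ = w · c_ref`, with `c_ref` the
concentration the reference was measured at. Fit quality is diagnosed
with the Durbin–Watson statistic of the residual (2 = no serial
correlation; structured, poorly fitted residuals push it toward 0), and
accuracy with the signed fractional error `(ĉ − c) / c`.

A synthetic-data module generates calibration libraries with the same
modes of variability (per-peak amplitude jitter, peak-position jitter, a
variable broad baseline bump, additive noise) and drives a leave-one-out
factorial study comparing the three estimators across a halving sequence
of analyte weights, `2⁰ … 2⁻¹³`.

## Worked example

```python
import ramanmix as rm

analyte    = rm.generate_library(rm.default_analyte_config(n_spectra=40, seed=0))
background = rm.generate_library(rm.default_background_config(n_spectra=60, seed=1))
model_a = rm.fit_pca(analyte.exclude(0), n_components=5)      # leave the analysed
model_b = rm.fit_pca(background.exclude(0), n_components=5)   # spectra out
axis = analyte.axis
mean_a = rm.Spectrum(axis, model_a.mean, label="analyte")
mean_b = rm.Spectrum(axis, model_b.mean, label="background")

v_true = 2.0 ** -6   # true analyte weight
measured = rm.Spectrum(axis, v_true * analyte.spectra[0] + background.spectra[0])

ls3p = rm.ClassicalLeastSquares(measured, [mean_a, mean_b], poly_order=3).fit()
hla  = rm.HybridLinearAnalysis(measured, model_b, mean_a, ref_concentration=0.8).fit()
hlp  = rm.HybridLSPCA(measured, [model_a, model_b], sigma=0.01).fit()
print(hlp.summary())
```

```
HLP unmixing results
====================
Method             HLP
Wavenumber points  700
Weight[0]           0.0180381
Weight[1]           1.04709
Residual norm      0.301532
Durbin-Watson      1.5938
Iterations         69 (converged)
Penalty beta       0.0001
Final cost         0.0914269
```

Comparing the three estimates of this one mixture (reference measured at
0.8 nM, so concentration = weight × 0.8 nM; true weight 0.015625):

```
method       weight   conc (nM)  frac err      DW
LS-3P      0.019552    0.015642    +0.251   1.078
HLA        0.018113    0.014490    +0.159   1.359
HLP        0.018038    0.014431    +0.154   1.594
true       0.015625    0.012500
```

HLP gives both the smallest fractional error and the residual closest to
serially uncorrelated (DW nearest 2) — it is the only estimator that lets
the background's narrow bands and the broad 1600–1800 cm⁻¹ bump flex
within their observed variability while also flexing the analyte
signature. The same comparison at scale (the leave-one-out factorial
study over all weight levels) is run by `ramanmix study` or
`run_factorial_study`, producing per-level fractional-error summaries and
per-method Durbin–Watson histograms.

## Command line

```sh
ramanmix simulate --kind background --n-spectra 60 --seed 1 --out bg.csv
ramanmix calibrate bg.csv --components 5 --out bg_model.json
ramanmix estimate-sigma replicates.csv
ramanmix fit mixture.csv --method hlp --model a_model.json --model bg_model.json \
         --sigma 0.01 --ref-concentration 0.8 --out fit.json
ramanmix study --subsample 10 20 --seed 0 --out study_out/
ramanmix report study_out/records.csv
```

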