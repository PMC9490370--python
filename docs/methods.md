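# Methods

## The measurement model

An EEM landscape records fluorescence intensity on a wavelength grid of
excitation columns and emission rows (default 200–600 nm in 10 nm steps,
41 points per axis).  For dilute solutions the analyte contribution is
bilinear in each landscape and trilinear across samples: sample *i*
contributes

    X[i, j, k] = Σ_a  c_ia · s_a · em_a[j] · ex_a[k]  + scatter[j, k] + ε

where `c_ia` is the concentration (µg/ml), `s_a` a sensitivity (intensity
units per µg/ml), and `em_a`, `ex_a` unit-maximum spectral profiles.  This
trilinear structure is what the N-PLS engine exploits; the contour-based
engines (LAR, iPLS) work on one emission column of it.

## Synthetic data generator

The generator reproduces the statistical structure the analysis assumes,
not the photophysics of real extracts.  Defaults, chosen once:

| parameter | default | reason |
|---|---|---|
| grid | 200–600 nm, 10 nm | instrument grid of the motivating study |
| analyte A (aesculin-like) | em 340/35 nm, ex 300/30 nm, s = 1000 | strong overlap with B (emission-profile Pearson r ≈ 0.89) |
| analyte B (aesculetin-like) | em 360/40 nm, ex 310/35 nm, s = 250 | as above; lower sensitivity so both span similar intensity ranges |
| concentration ranges | 0.002–1.020 and 0.009–4.000 µg/ml | the study's calibration ranges |
| concentration sampling | log-uniform | the ranges span ~3 decades; uniform sampling would starve the low end |
| n_samples | 21 | study size; splits 16 + 5 at 3/4 |
| noise | Gaussian, sd = 1 % of each sample's max clean signal | plausible detector noise; no noise model is published |
| Rayleigh ridges | Gaussian cross-section, sd 5 nm; amplitudes 50 % (first order) and 25 % (second order) of the max single-analyte signal | ridge width at the monochromator-bandpass scale, below the grid step |
| Raman ridge | 3400 cm⁻¹ shift from excitation, sd 5 nm, amplitude 5 % | aqueous solvent convention |
| spiked pairs | 6 pairs; spike amounts 0.48/0.50/0.48/0.48/0.25/0.40 (A) and 2.00/2.30/2.00/2.00/1.00/1.50 µg/ml (B); base levels log-uniform over (hi/40, hi/4) | bench-scale spike levels; base + spike stays inside the calibrated range |

All randomness flows from one seed through `numpy.random.default_rng`;
regeneration is bit-stable.  The pipeline derives per-stage child seeds by
hashing the stage name (CRC-32 XOR seed, reduced below 2³¹), so adding a
stage never perturbs earlier stages.

What the generator does **not** emulate: inner-filter effects, quenching,
pH-dependent intensity, anti-Stokes suppression (profiles are pure
Gaussians, so a little "emission" occurs below the excitation line — real
spectra are dark there), background fluorophores of a real plant extract,
and replicate measurement structure.  Tests passing on this generator
demonstrate the algorithms' correctness and their behaviour under overlap,
scatter and noise — not performance on real extracts, where unknown
interferents typically demand extra latent variables.

## Scatter handling

`build_scatter_mask` marks cells within half-widths w₁, w₂, w_R of the
first-order Rayleigh line (λ_em = λ_ex), second-order line (λ_em = 2 λ_ex)
and Raman line (fixed wavenumber shift); defaults 15/15/10 nm on the 10 nm
grid, wide enough that residual ridge intensity outside the mask is below
1 % of peak for the generator's ridge widths.  A width of zero still masks
cells exactly on the ridge.  The mask keeps its per-ridge components
alongside the union, and is monotone in the widths.

`excise_and_interpolate` refills each masked cell with the average of two
1-D cubic-spline interpolations through the unmasked cells — one along the
cell's emission column, one along its excitation row (constant extrapolation
beyond the outermost anchors; plain linear interpolation when fewer than
four anchors exist; zero fill with a warning if neither direction has any
anchor).  A cubic spline rather than a linear segment is used deliberately:
when the excision band crosses a spectral peak — which happens here, the
Rayleigh band crosses the emission maximum near λ_ex ≈ 330 nm and the Raman
line crosses it near λ_ex ≈ 300 nm — a linear fill truncates the band by
roughly 9 % of the peak signal, while the spline reconstructs the curvature
from the flanks and stays within about 2 %.  Both variants are exact on
affine surfaces and idempotent (anchors are never themselves refilled values
because the non-fluorescent triangle λ_em < λ_ex outside the scatter bands
is zeroed *before* interpolation; that zeroing reflects the physical
darkness of the anti-Stokes region and can be disabled).

## Calibration/prediction split

The calibration size is round-half-up(fraction · n), clamped to [1, n−1]:
21 samples at 3/4 give 16 + 5, which forces the half-up rule (15.75 → 16).
Samples are ranked by the target analyte's concentration and every
(n // n_pred)-th rank is held out — deterministic, concentration-stratified
systematic sampling, so the held-out samples span the range instead of
clustering at one extreme.

## Model selection statistics

RMSECV = √(Σ(yᵢ − ỹᵢ)²/m) and PRESS = Σ(yᵢ − ŷᵢ)² are both computed from
leave-one-out predictions throughout (the identity PRESS = m·RMSECV² links
them).  LOO is used uniformly because the calibration set is small (16) and
it is the scheme under which both statistics are defined here; k-fold
variants are out of scope.

## LAR (lasso) engine

Cyclic coordinate descent with covariance (Gram) updates solves
`min (1/2m)‖y − β₀ − Xβ‖² + λ‖β‖₁`.  Predictors are centered and scaled to
unit variance internally and the solution back-transformed, so reported
coefficients live on the raw contour-intensity scale; zero-variance columns
are left at zero.  Convergence requires a per-sweep max coefficient change
≤ 1e-10 or a duality gap ≤ 1e-8 (the gap uses the scaled residual dual
point; at λ = 0 the gap degenerates and the coefficient criterion governs).
The final fit warm-starts along a short geometric penalty path; the CV path
inside `select_penalty` uses a relaxed gap (1e-5) since RMSECV is
insensitive at that level.

`select_penalty` scans a log grid from the null-model penalty λ_max down
four decades.  Two rules are exposed: `"min"` (default) takes the RMSECV
minimizer, ties to the larger penalty; `"1se"` takes the largest penalty
within one standard error of the minimum CV mean squared error.  The 1-SE
option exists because on small, collinear designs (16 samples × 41
correlated contour variables) the LOO curve can keep drifting down at tiny
penalties purely by chance, and the min rule then returns a dense model even
for pure-noise responses; the 1-SE rule is the standard guard.

Negative predicted concentrations are reported as-is with a warning flag;
recovery arithmetic on spiked pairs needs the raw values.

## iPLS engine

Variables are partitioned into contiguous intervals of near-equal width
(base width floor(n/k); the remainder widens the trailing intervals, so 41
variables in 8 intervals give 5,5,5,5,5,5,5,6).  For every interval and
every component count up to min(10, interval width, m−2) a local PLS1
(NIPALS, centered, unscaled) is cross-validated; the argmin of the RMSECV
table wins, ties resolving to fewer components and then the lower interval
index (parsimony before position).  The returned model stores the full
table for inspection and is refitted on all calibration samples.

## N-PLS engine (tri-PLS1)

Centering only, across the sample mode (mean slab and mean y); no scaling —
standard second-order calibration practice and required for the centering
identities (a sample equal to the mean slab predicts mean y).  Per factor:
`Z = Σᵢ y_res,i · X_res,i` (emission × excitation); the leading singular
pair of Z gives unit-norm weights (SVD sign ambiguity fixed by making the
largest-magnitude element of the emission weight positive, flipping both
weights together, so fitting is bitwise deterministic); scores are
`tᵢ = Σ_jk X_res,ijk w_j w_k`; y is regressed on all scores so far; X and y
are deflated.  Degenerate residuals truncate the factor count, and a fully
degenerate model predicts mean(y).  Prediction pushes new samples through
the same stored deflation pipeline.

LV count selection: leave-one-out PRESS, `"global"` minimum by default
(ties to fewer LVs), `"first local minimum"` as an option — on real
extracts with background interferents the PRESS curve may dip locally well
before its global minimum, and stopping there avoids modelling noise.  On
the two-analyte synthetic design the global rule selects 2 LVs, the
chemical rank.

## Validation

Rc/Rp are Pearson product-moment correlations (the plain "correlation
coefficient"; not R², not through-origin).  RMSEC/RMSEP use the
m-denominator, matching the RMSECV formula.  Replicate measurements of one
physical sample, when labelled, are averaged on the predicted-concentration
scale before metrics.  Spike recovery is 100·(Con1 − Con0)/Cons and is
reported unclipped.

## Problem sizes and numerical choices

The shipped study conditions are desk-scale: 21 standards + 6 spiked pairs
of 41×41 landscapes; the full pipeline (all three engines, both analytes)
completes in a few seconds, and the repetition study of spike recovery uses
100–200 independent regenerations of the whole design.  Numeric output is
serialized at 12 significant digits; wavelength-grid equality is exact;
scatter-mask width comparisons carry a 1e-9 nm tolerance to absorb float
representation only.  Known limitations: no handling of missing cells
inside the cube (infilling is preprocessing's job), no N-PLS2 / PARAFAC, no
inner-filter correction, and the interval boundaries of iPLS are fixed by
the equal-width rule rather than optimized.
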