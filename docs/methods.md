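# Methods

This note documents the models implemented in `ivtkit`, the assumptions
behind the synthetic-data generators, and the numerical and design choices
made where a convention had to be fixed. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## SHAPE-MaP reactivity

Chemical probing with NAI acylates the 2′-hydroxyl of conformationally
flexible nucleotides; reverse transcription converts adducts into
mutations. For one RNA, one replicate, and channels NAI and DMSO the
pipeline computes

* mutation rate per position: mutations / coverage, undefined (NaN) at
  zero coverage rather than zero;
* raw reactivity: rate(NAI) − rate(DMSO), negatives retained;
* normalized reactivity: raw / (1.5·(Q₃ − Q₁)), with Q₁/Q₃ the 25th/75th
  percentiles of the raw reactivities of that RNA.

Conventions fixed here (each configurable where noted):

* **Replicate pairing.** NAI replicate k is subtracted against DMSO
  replicate k, preserving replicate-level variance for the downstream
  differential test (rather than subtracting an averaged DMSO background).
* **Quartile estimator.** Linear interpolation between closest order
  statistics (`numpy.percentile(..., method="linear")`); fixed for
  reproducibility. Worked check: raw [0, 1, 2, 3] gives Q₁ = 0.75,
  Q₃ = 2.25, scale 2.25.
* **Quartiles per replicate, after the coverage filter.** Each replicate
  profile is normalized on its own quartiles, computed over
  coverage-passing positions by default (`quartiles_after_filter=False`
  switches to all defined positions). Normalization is scale-invariant and
  forces the IQR of the normalized values to 1/1.5 exactly.
* **Coverage rule.** A position is reportable only when coverage strictly
  exceeds the threshold (default 10 000 reads) in *every* contributing
  channel. Masking is monotone in the threshold.
* **Mean profile.** Per-position mean of normalized values across
  replicates; a position failing the coverage rule in any replicate is
  masked in the mean, keeping the replicate count (hence the variance of
  the mean) constant across positions. Negative means are retained in data
  files; plotting layers are expected to exclude them.
* **Coordinates.** 1-based inclusive everywhere; insertions counted at the
  5′-most reference position they follow, deletions at their first deleted
  position. SHAPE constraint files use the conventional `index value`
  lines with −999 for masked positions.

## Differential reactivity (moderated t-test)

Normalized reactivities are square-root transformed. Negative inputs are
clamped to zero before the square root (they arise when the NAI rate falls
below the DMSO background by chance) and the clamped positions flagged. A
per-position two-group linear model gives effect = mean(A) − mean(B) and
pooled within-group variance s² on d = n_A + n_B − 2 degrees of freedom
(equal-variance pooling, matching standard linear-model semantics, not
Welch).

The empirical-Bayes step assumes s²_g | σ²_g ~ σ²_g χ²_d / d with a scaled
inverse-χ² prior on σ²_g parameterised by (d₀, s₀²). The marginal of
z = log s² then has closed-form mean and variance through digamma /
trigamma functions, and (d₀, s₀²) are estimated by matching the empirical
moments of z, inverting the trigamma function by Newton iteration. When
the excess variance of z is non-positive the prior is infinitely
informative: d₀ = ∞, every posterior variance equals s₀² (the
moment-matched, log-χ²-bias-corrected value), and the reference
distribution is normal. Otherwise

    s̃²_g = (d₀ s₀² + d s²_g) / (d₀ + d),
    t_g = effect_g / sqrt(s̃²_g (1/n_A + 1/n_B)),

with two-sided p-values from t on d + d₀ degrees of freedom (capped at the
pooled residual degrees of freedom of all testable positions). Setting
d₀ = 0 disables moderation and reproduces the classical pooled t-test
exactly. The implementation agrees with Bioconductor limma (`lmFit` +
`eBayes`) to machine precision; the test suite performs that cross-check
through `Rscript`.

Significance is declared by the fixed strict rule P < α with α = 0.001 and
no multiplicity correction, matching the convention of the assay this
pipeline serves; a Benjamini–Hochberg helper is available but off by
default.

## 4PL dose-response and apparent K_d comparison

Model: OD(c) = Bottom + (Top − Bottom)/(1 + (K_d/c)^Slope), fitted by
bounded least squares (trust-region reflective) with K_d parameterised on
the log₁₀ scale. Defaults: Bottom constrained to 0 for blank-corrected
data (K = 3 fitted parameters; a free-Bottom variant with K = 4 serves the
IFN-β standard curve). Initialisation Top₀ = max OD, K_d₀ = geometric mean
of the concentration range, Slope₀ = 1; bounds K_d ∈ [min c/100,
max c·100], Slope ∈ [0.1, 10]; three perturbed restarts on
non-convergence. Zero-concentration wells are blanks (mean-blank
subtraction, negatives retained), never fit points, since the model is
undefined at c = 0. A concentration span under 2 log units triggers a
warning.

**ROUT outlier removal** (Q = 1% by default): a robust fit minimising the
Lorentzian merit Σ ln(1 + (r/RSDR)²) — implemented as Cauchy-loss least
squares with the scale fixed at the current RSDR and iterated to a fixed
point — where RSDR is the 68.27th percentile of |residuals| times the
small-N correction N/(N−K). Each point receives a two-tailed p-value from
t = |r|/RSDR on N−K df; points are tested most-extreme-first against
α_i = Q(N−i+1)/N and flagging stops at the first non-significant point.
The final least-squares fit excludes flagged points; if more than 30% of
the data would be dropped the exclusion is refused with a warning
(overridable). ROUT runs per dataset, before the separate and the joint
fits, on the same exclusion set.

**Model comparison.** The separate model fits independent (Top, K_d,
Slope) per dataset (Bottom = 0 in both, K = 6); the shared model shares
K_d only, leaving Top and Slope dataset-specific (K = 5) — assay ceilings
and slopes differ between cell lines, so only the potency parameter is
constrained; sharing more parameters is configurable. AICc uses the
residual-sum form N·ln(SS/N) + 2K + 2K(K+1)/(N−K−1) over the joint N, with
K counting fitted curve parameters only (no +1 for the error variance; the
convention cancels from ΔAICc as long as it is applied to both models).
ΔAICc = AICc_shared − AICc_separate, and Akaike's probability
1 − (e^(ΔAICc/2)+1)^(−1) = expit(ΔAICc/2) is reported as the evidence
weight of the separate-K_d model (0.5 at ΔAICc = 0, 0.75 at ΔAICc = 2 ln 3).

A caveat worth recording: with two datasets of 8 concentrations in
quadruplicate (joint N = 64) the AICc penalty difference between the
models is ≈ 2.44, so under a truly shared K_d the shared model is
preferred with probability ≈ P(F(1,58) < 2.25) ≈ 0.85–0.90, not near 1;
parsimony selection at this design size retains an irreducible ~10–15%
rate of spurious separate-model preference. The acceptance statistics
report the empirical rate.

**IFN quantification.** The standard curve (≥ 4 serial dilutions of
recombinant IFN-β, free Bottom) is inverted analytically; sample ODs at or
below the fitted value at the lowest standard are left-censored at the
lower limit of quantification, at or above the highest standard
right-censored, and never extrapolated beyond the asymptotes. Reported
concentrations are multiplied by the sample dilution factor (e.g. 7 for
1:7 predilutions).

## Spearman–Kärber endpoint titration

With dilution exponents x_i = log₁₀(reciprocal dilution), equally spaced
with step d, and infected proportions p_i, the estimate is

    log₁₀ CCID50 = x₀ + d (Σ p_i − 0.5),

anchored at the lowest exponent with the sum over all dilutions — one of
several equivalent statements of the formula, fixed here and verified by
the worked example p = [1,1,1,1,0.5,0,0,0] on exponents 1–8 → 5.0. The
estimator requires p = 1 at the lowest and p = 0 at the highest exponent;
otherwise the result is a censored bound (">" or "<"), never a number.
Adding a fully infected dilution below the series or a fully uninfected
one above leaves the estimate unchanged (the anchor shift and the added
proportion cancel exactly). Per-volume normalisation is a reporting
multiplier on the log scale.

The companion generator uses a single-hit model: a well inoculated at
exponent x is infected with probability 1 − exp(−ln 2 · 10^(T − x)), so
that the infected proportion crosses ½ exactly at x = T — i.e. the truth T
is a genuine CCID50 (one CCID50 = ln 2 infectious units, the standard
conversion between endpoint and particle-count titers). Without the ln 2
factor the Spearman–Kärber estimator would target the mean of a Gumbel
curve 0.25 log units above the Poisson intensity parameter; with it the
residual bias is γ/ln 10 − log₁₀(ln 2) ≈ +0.09 log units, which the
acceptance statistics measure.

## Dot-blot densitometry

Spot intensity is modelled as linear in log₁₀(amount) — a good description
of chemiluminescent dot intensity over two-fold dilution series; the
default standard series is the Φ6 dsRNA ladder [500, 250, 125, 63, 31,
16] pg. Apparent saturation (top standard carrying the largest, negative
residual) and non-monotone series raise warnings rather than switching to
a binding model. Interpolation is the exact inverse of the fitted line;
intensities outside the standards' fitted range are censored to the
nearest standard amount with a flag. Group fold differences are ratios of
group means over uncensored estimates, with censored counts reported;
contamination fractions divide estimated dsRNA by the loaded total.

## Image cytometry

Segmentation is deliberately the simplest reproducible chain: optional
Gaussian smoothing (segmentation only; intensities are always measured on
the raw image), a global threshold (default 200, distinct from and below
the intensity gate), and 8-connected component labelling. An object is
counted when its occupied area lies within 150–800 μm² (both bounds
inclusive; the source convention does not specify open/closed) and its
mean intensity is ≥ 400 (inclusive). Intensity units are
instrument-specific, so 400 is an honoured default, not a calibrated
value. Flat-field correction is approximated by optional division by a
large-sigma Gaussian background estimate. Raising the intensity threshold
can never increase the count and widening the area window can never
decrease it.

## Synthetic-data generators

All generators draw from `numpy.random.default_rng(seed)` and return a
ground-truth record; identical parameters and seed reproduce outputs
bit-identically.

* **Structured reactivity.** Paired positions (from a dot-bracket string)
  draw Gamma(2, 0.02) reactivities (mean 0.04), unpaired positions
  Gamma(4, 0.2) (mean 0.8) — mimicking the bimodality of normalized SHAPE
  profiles. Values are drawn in position order so the profile layout
  follows the structure.
* **SHAPE counts.** Coverage is Poisson with the stated mean (default
  50 000; real deep-sequencing coverage is overdispersed relative to
  Poisson, an accepted simplification at this scale). DMSO mutation counts
  are binomial at a constant background rate (default 0.002; optional
  per-position jitter), NAI counts binomial at background +
  sensitivity·reactivity (default sensitivity 0.02 — the adduct-to-
  mutation conversion efficiency is not an externally known constant, so
  this is a free generator knob).
* **Dose-response.** OD = 4PL + N(0, noise_sd); exactly
  round(fraction·N) points are additionally displaced by ±outlier_scale·
  noise_sd with random sign. Displacement (rather than merely inflating
  the noise variance) keeps injected outliers tied to the noise scale
  while guaranteeing they are gross: zero-mean noise scaled 10× would
  leave roughly a fifth of "outliers" within the detection threshold of
  any reasonable flagging rule, making recovery rates meaningless.
* **Endpoint dilution.** Single-hit model with the ln 2 CCID50 convention
  described above.
* **Dot blot.** Intensities a + b·log₁₀(amount) (defaults a = 10, b = 40)
  with multiplicative Gaussian noise; unknowns from the same curve.
* **Cell images.** Constant-intensity disks placed without overlap by
  rejection sampling (bounded retries, then an error): gate-passing disks
  at 200–700 μm² and intensity 600–2000, area-failing disks at 40–100 μm²,
  intensity-failing disks at 250 (segmentable but below the 400 gate);
  optional Gaussian background noise.

What passing the recovery tests does **not** show: robustness to
overdispersed coverage, alignment or PCR artifacts in probing data,
heteroscedastic or drifting plate reads, non-log-linear blot saturation,
or irregular cell morphology and clumping — the generators emulate the
models' assumptions, so the tests validate the estimators, not the
assay chemistry.

## Problem sizes and numerics

Recovery statistics are computed at desk scale: 100 simulations for the
dose-response, ROUT and blot statistics; 20 seeds for SHAPE recovery; 100
runs × 1000 positions (10⁵ position-tests) for the null calibration of
the moderated test; 200 simulations for titration. Least-squares
tolerances are 1e-13 (noiseless 4PL parameters reproduce to ≲1e-9
relative); the trigamma inversion converges to 1e-10; JSON and TSV reals
are serialised with 6 significant digits so repeated runs are
byte-identical. Degenerate inputs are errors, not silent results: zero
spread in raw reactivities (Q₃ = Q₁), constant ODs (unidentifiable slope),
fewer than 8 unmasked positions, fewer than 10 ROUT points, unbracketed
titration series.

## Known limitations

* The shared-K_d comparison is implemented for the Bottom = 0
  parameterisation used by the reporter assay; free-Bottom joint fits are
  out of scope.
* ROUT's breakdown point is that of its Lorentzian M-estimator: with
  contamination fractions approaching 50% the robust fit loses the
  consensus curve and flags nothing (the mass-exclusion guard then refuses
  to act); it is reliable in the ≤ 30% regime it is specified for.
* The moderated test assumes exchangeable per-position variances around a
  single prior; reactivity-dependent variance heterogeneity is absorbed
  into a finite d₀ but not modelled explicitly.
* Image analysis is single-channel with a global threshold; live/dead
  gating, confluence normalisation and tracking are out of scope.
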