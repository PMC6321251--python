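# Methods

## The calibration problem

Given n samples with log(1/R) reflectance spectra x_i on a uniform
wavelength grid (default 400–2498 nm at 2 nm, 1050 points) and a scalar
reference value y_i per analyte, the task is a linear calibration
ŷ = f(x) whose predictive quality is judged by external validation. The
package follows the standard NIRS recipe: pretreat, screen outliers, split,
select model size by cross-validation, fit, validate.

## Pretreatment

**SNV** standardises each spectrum to mean 0, sample sd 1 (ddof = 1).
It removes multiplicative scatter and additive offset exactly: for
x' = a·x + b (a > 0), SNV(x') = SNV(x). A constant spectrum is a
degenerate input and raises an error. **De-trending** subtracts the
least-squares polynomial (degree 2 by default, configurable) of absorbance
on wavelength, removing curvilinear baseline drift; the residual is
orthogonal to the polynomial basis. SNV-DT is applied to log(1/R) *before*
derivation — the order is not universal in the literature, so it is a
documented choice here, not an asserted equivalence with any commercial
package.

**Gap-segment derivatives** use the 4-number treatment d,g,s₁,s₂ with all
parameters in data points (1 point = 2 nm). The pipeline is: centered
boxcar running mean of width s₁ (even widths round up to odd) → symmetric
gap difference (order 1: x[i+g] − x[i−g]; order 2: x[i+g] − 2x[i] + x[i−g])
→ boxcar of width s₂. Every stage only emits points whose full stencil lies
on the grid, so (s−1)/2 points per smooth and g points per derivative are
trimmed from each edge and the surviving grid is reported; nothing is
padded or extrapolated. The operator is linear, maps constants to zero
(order ≥ 1), and has the closed forms 2·g·slope on a ramp (order 1) and
2·g² on x[i] = i² (order 2), which the tests pin down along with a
direct-summation oracle. The gap/smoothing arithmetic of the commercial
software that popularised this notation is proprietary; this convention is
documented rather than claimed equivalent.

## Regression: PLS1 and modified PLS

NIPALS PLS1 on mean-centred data: w ∝ Eᵀf (unit norm), t = Ew,
p = Eᵀt/tᵀt, q = fᵀt/tᵀt, then deflate E and f. X is always centred; y is
centred but never scaled, so coefficients carry the reference units.

**MPLS (Shenk–Westerhaus modification).** Before extracting each factor,
every wavelength column of the current X-residual matrix is divided by its
residual standard deviation (columns with zero residual variance keep
scale 1 — the documented degenerate rule). The per-factor scale vectors are
stored on the model and replayed at prediction time, so prediction is an
exact linear map and serialised models reproduce predictions bit-for-bit.
Forcing all scales to 1 reduces MPLS to PLS exactly; this switch is kept as
a correctness anchor in the tests. Only X-residuals are rescaled; y is
left alone. Only PLS1 is provided — each analyte is calibrated
independently, mirroring the separate TPC and TCC models.

The regression vector exposed by `CalibrationModel.coefficients` is
computed by pushing the identity basis through the factor replay, which is
exact for arbitrary scale histories.

## Factor selection and validation statistics

Cross-validation partitions the calibration set into n_groups seeded
random folds (default 5; the seed is recorded in every report). One model
per fold is fitted at the maximum factor count and scored at every
truncation, giving SECV(k) = RMS cross-validated residual. The chosen
count is the smallest within 1e−9 of the SECV minimum — a medium-sized
model is preferred over a marginally better large one. The factor search
is capped at the minimum training-fold rank, since exactly low-rank data
(e.g. noise-free simulations) make NIPALS degenerate past the rank.

Statistics: SEC = √(SSE/(n−k−1)) with k the number of latent factors;
SEP = √(Σ(e−bias)²/(n−1)) with bias = mean(ŷ−y); R² and Q² are coefficients
of determination about the reference mean (R²cv is 1 − PRESS/SST);
RPDcv = SD/SECV, RPDp = SD/SEP, RER = range/SEP. A widely printed variant
of the RPD/RER denominator uses "N − K − 1" with K the number of
wavelengths, which is undefined when K exceeds N; interpreting K as the
number of model factors (for SEC) and using the bias-corrected n−1 form
(for SEP) is the only reading consistent with the published arithmetic this
package reproduces (e.g. 1.85/1.22 = 1.52). Reports round to 2 decimals at
the formatting layer only; full precision is kept internally.

Quality bands: Q² <0.26 none / 0.26–0.49 low correlation / 0.50–0.64 rough
prediction / 0.65–0.81 discriminate low-high / 0.82–0.90 good / >0.90
excellent; RPD <1.5 unusable / 1.5–2.5 screening / 2.5–3 good / >3
excellent; RER ≥ 10 quantitative. Band edges are half-open upward, so a
value sitting exactly on a boundary takes the higher label.

## Outlier screening (global H)

The preprocessed spectra are decomposed by SVD; principal components are
retained up to 99% explained variance (capped at n−2 and at the numerical
rank, with a warning when the matrix is rank-deficient). GH_i is the
squared Mahalanobis distance of sample i in score space divided by the
number of retained components; mean GH ≈ (n−1)/n by construction. Samples
with GH > 3 are flagged and removed once before calibration — there is no
iterative elimination loop. Note that a gross outlier inflates the leading
component variances, so the 10-sd-displacement detection guarantee applies
to tight, low-dimensional clouds, not to isotropic noise.

## Calibration/validation split

Deterministic and positional: 1-based positions step, 2·step, … go to
validation, the remainder to calibration (default step 5, giving a 4:1
ratio — 96/24 from n = 120). A step of 4 reproduces a 3:1 (90/30-style)
ratio when that is wanted. The partitions are disjoint and exhaustive by
construction.

## Synthetic studies

The generator emulates the statistical structure the analysis assumes:

* **Reference values** are truncated-normal (exact rejection sampling):
  TPC mean 24.27, sd 3.06, range [17.36, 35.67] mg GAE·g⁻¹ dw; TCC mean
  8.30, sd 1.82, range [2.84, 13.73] µg·g⁻¹ dw; n = 120; TPC–TCC
  correlation defaults to 0.
* **Spectra** are additive Beer–Lambert mixtures: a constant baseline
  (0.5 AU), each analyte's unit-normalised Gaussian-band component scaled
  linearly with concentration (peak 0.30 AU for phenolics, 0.15 AU for
  carotenoids at the mean concentration), and interfering constituents
  (water 0.80 AU ± 10%, sugars 0.40 ± 20%, lipids 0.20 ± 20%, cellulose
  0.30 ± 15%, chlorophyll 0.25 ± 30%) with per-sample lognormal-like
  variation. Band centres follow the constituent assignments (phenolics in
  1415–1512 and 1955–2035 nm; carotenoid C–H at 1100–1250, 1300–1350,
  1650–1700 nm plus the 450 nm electronic band; chlorophyll 674 nm; sugars
  1436 nm; water 1404/1924 nm; lipids 1724/2300/2350 nm; cellulose
  2278/2388 nm); widths default to ~30 nm in the visible and 35–80 nm in
  the NIR — plausible overlap, not asserted physics.
* **Artefacts**: per-sample multiplicative scatter (sd 0.10), additive
  offset (sd 0.05), linear tilt (sd 0.02 across the grid) — exactly the
  corruptions SNV-DT targets — plus iid instrument noise (sd 0.001 AU,
  typical of research-grade NIR instruments).

One integer seed drives all draws; identical seeds give bit-identical
studies.

**What the generator does not emulate**: real covariance between
constituents, wavelength-correlated noise, instrument nonlinearity,
temperature/moisture effects, or any matrix interference beyond additive
band overlap. Passing tests therefore demonstrate the correctness of the
algorithms under the model's assumptions, not field performance on real
fruit spectra. One consequence worth knowing: SNV's per-sample
normalisation is nonlinear in the constituent concentrations, so when
interferent variability is large the noise-free calibration ceiling drops
below Q² = 1 (≈0.84 for the phenolics analyte under the defaults). The
"signal-dominated limit" property test accordingly uses mild interferent
variability (relative sd 0.02), where Q² recovers to >0.99.

## Problem sizes

The default study is n = 120 spectra × 1050 wavelengths, 5-fold
cross-validation, factor search to 16, four treatments × two analytes;
a full run completes in roughly a second, and the whole test suite in well
under a minute. These sizes were chosen to mirror the study population
while keeping simulations instant to rerun.

## Known limitations

* The gap/smooth convention and the MPLS scaling variant are documented
  reconstructions of partially proprietary algorithms; numerical equality
  with commercial software output is not claimed.
* Q²/R² are computed as 1 − SS_res/SS_tot; software that reports squared
  Pearson correlation will differ when predictions are biased.
* The CENTER screen runs once; iterative outlier elimination and
  chemistry ("T") outliers are out of scope.
* The reference-assay helpers encode unit arithmetic only; standard-curve
  parameters and the carotenoid absorptivity are user inputs (the 2592
  default is the common β-carotene-in-petroleum-ether value).
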