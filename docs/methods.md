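# Methods

## Quantitation model

**Targeted analytes.** Quantitation is classical isotope dilution: every
targeted analyte has an isotopically labeled internal standard (IS) spiked at
a fixed amount (0.1444 pmol: 38 µL of a 3.8 nmol/L mix into 500 µL of
sample), and the measured quantity is the response ratio
`R = analyte area / IS area`. Calibration regresses `R` on the nominal
calibrant concentration with weighted least squares; the default weighting is
`1/x²`, the standard choice when a curve spans four decades, because
multiplicative (constant-CV) detector noise makes the absolute residual
variance grow as `x²`. Weighting is configurable (`none`, `1/x`, `1/x²`).
Back-calculation inverts the line. A curve is accepted when the back-calculated
calibrant concentrations are within ±15% of nominal (±20% at the lowest
level) for at least 75% of levels; the valid range `[LLOQ, ULOQ]` is the span
of passing levels, and out-of-range unknowns are flagged (`below_lloq`,
`above_uloq`) rather than suppressed. A declared dilution (e.g. 1:4)
multiplies the back-calculated value before range flags are applied.

**Untargeted analytes (surrogate calibration).** An untargeted analyte `u`
has a reference mass and retention time but no routine calibrants. Its
response is pushed through the calibration curve of a surrogate `s` —
androstenedione (A4) for C19 steroids, progesterone (P4) for C21 steroids —
yielding an apparent concentration in surrogate equivalents. Since both
compounds' curves are linear over the design range, the apparent
concentration differs from truth by a constant reflecting their electrospray
ionization-efficiency difference. The correction factor is derived from a
matched calibration series of `u` as the zero-intercept weighted (`1/x²`)
regression slope of true on apparent concentration; with that weighting the
estimator reduces to the mean of per-level `true/apparent` ratios, which
keeps every decade equally influential. The factor is accepted as constant
when each per-level ratio is within ±15% of the pooled value. Whether the
regression is run response-on-response or concentration-on-concentration is
immaterial for linear zero-intercept curves: both give the same multiplier;
the concentration domain is used because it makes "multiply the apparent
concentration by the factor" exact by construction. Only the 11KA4 factor
(0.329 vs A4) ships as a verified value; all other packaged factors are 1.0
placeholders whose results carry an `unverified_factor` flag.

The IS used to normalize an untargeted analyte is the nearest in retention
time (ties break toward the earlier-eluting standard), since with 13
standards spread over the elution range the nearest standard best tracks
local matrix effects.

**Agreement analysis.** Targeted-vs-untargeted agreement for dually
quantifiable analytes is summarized by OLS of untargeted on targeted
concentration; the slope captures the constant bias surrogate calibration can
introduce (typically 10–30% when matrix effects are not fully cancelled), and
the offset is reported as % of the median targeted concentration.

## Chromatographic processing

XICs are extracted from centroided scans at a fixed absolute tolerance of
5 mmu (0.005 Th) — absolute, not ppm, appropriate for a narrow 200–500 m/z
steroid window. Peak integration: the apex is the maximum within ±0.2 min of
the expected RT; bounds are walked outward until intensity falls below 0.1%
of the apex or a local minimum below 5% of the apex; the area is the
trapezoidal integral above a straight baseline between the bounds. The 0.1%
boundary keeps the truncation-plus-baseline bias of a Gaussian peak near
0.3% (a 1% boundary would bias areas by ~2.7%). A peak is `not_detected`
when the apex does not exceed 3× the median intensity outside the search
window. All thresholds are module constants; none are instrument-derived —
they replace vendor-software defaults and are stated here so results are
reproducible.

## Validation battery

`rsd_percent` (100·SD/mean, dispersion) and `relative_error_percent`
(100·(mean−nominal)/nominal, signed bias) are computed per analyte and level
from replicate QC sets (6 replicates × 4 levels × 3 days by design).
Pass rules: both metrics within ±20% at the LLOQ and ±15% at low/mid/high;
comparisons are inclusive (≤) at the threshold. Inter-day metrics pool all
days; intra-day metrics are per day. Carryover in a solvent blank injected
after the highest calibrant passes when the blank signal is strictly below
20% of the LLOQ signal. The LLOQ finder returns the lowest candidate level
whose metrics stay within ±20% on every day. Some published validation
tables label RSD "Accuracy" and relative error "Precision" — the reverse of
the conventional mapping; code names metrics by formula and the report
renderer offers a `--paper-labels` mode reproducing the swapped headers.

## Pathway statistics and classifiers

Apparent enzyme activities are product-to-substrate concentration ratios
(`CYP17A1 = 17OHP4/P4`, `HSD3B2 = P4/P5`, `HSD11B2 = cortisone/cortisol`,
etc.); the default table contains only main-pathway ratios and is extensible
via panel config. Any missing or below-LLOQ constituent makes a ratio or
classifier undefined (NaN) — below-LLOQ values are never imputed (no LLOQ/2
substitution), because a fabricated denominator would silently distort a
ratio. The phase classifiers are fixed composite scores, not fitted models;
the serum and PF classifiers carry concentration units (numerator nmol/L over
a dimensionless activity), so their values scale with the unit — documented
rather than "fixed", since only relative group separation is interpreted.

Group comparisons log₁₀-transform (excluding non-positive values), z-score,
then use Kruskal–Wallis across phases and pairwise two-sided Mann–Whitney
tests with Benjamini–Hochberg adjustment; exact Mann–Whitney null
distributions are used for tie-free groups up to n = 25, the normal
approximation otherwise. Stars: `*` < 0.05, `**` < 0.01, `***` < 0.001,
`****` < 0.0001. Nonparametric tests were chosen because phase groups are
small (9–16) and steroid concentrations are right-skewed; the choice is a
package decision, configurable, and not claimed to match any specific prior
software.

## Correlation analysis

Spearman matrices use pairwise-complete observations, average ranks for
ties, and two-sided p-values from the exact permutation null when n ≤ 9
(all n! rank permutations enumerated) and the t-approximation otherwise.
Heat-map ordering is average-linkage hierarchical clustering on `d = 1 − ρ`;
undefined cells are imputed as ρ = 0 and flagged. Linkage and distance are
choices of convenience for display — no claim is made that cluster-box
boundaries of any particular published figure are reproduced. Serum-vs-PF
comparison uses per-analyte medians over paired subjects, the serum/PF median
ratio, and OLS of PF on serum with its p-value; analytes with fewer than 3
complete pairs are skipped with a reason.

## Synthetic data

The generators define the study conditions under which the package is
tested:

* **Calibration**: 12 geometric levels over 0.1–2000 nmol/L; responses are
  `slope·conc` with log-normal noise (CV 5%); the true slope of an untargeted
  analyte is `surrogate slope / correction factor`, encoding the ionization
  difference the factor must recover. IS areas are constant (5×10⁵) ±noise.
* **QC**: 6 replicates × 4 levels × 3 days, configurable per-level bias/CV.
* **Cohort**: 11/16/11/9 subjects (menstruation/proliferative/secretory/
  dienogest), paired serum + PF rows. Between-subject biology is log-normal
  with GSD 1.6 around class-typical medians (e.g. cortisol 250, DHEA-S 2000,
  aldosterone 0.35 nmol/L); progestogens ×2.5 in PF, corticoids and androgens
  ×2 in serum; the secretory phase multiplies P4 and its direct metabolites
  by 10 in both matrices; dienogest multiplies progestogens by 0.2. These
  multipliers are plausible effect sizes chosen once to reproduce the
  qualitative structure of a real cycle cohort; true between-subject
  variances are unknown and the defaults are not measurements.
* **Scans**: Gaussian elution peaks (σ = 0.02 min, scans every 0.005 min)
  at each analyte's (m/z, RT); centroid m/z error is uniform within ±2 mmu,
  always inside the 5-mmu XIC window. Peak area is
  `slope·conc·IS-area·recovery` with recovery (default 0.85) applied to both
  analyte and IS peaks, so the response ratio is recovery-free as in real
  isotope dilution.

What the generators do **not** emulate: isotope envelopes and spectral fine
structure, retention-time drift between runs, co-eluting isobars closer than
the panel's RT spacing, heteroscedastic electronic noise, and non-constant
matrix effects. Passing tests therefore demonstrate correctness of the
computational pipeline under its stated noise model, not instrument-level
robustness.

All generators are pure functions of (config, seed); independent RNG streams
are derived per generator so adding one stage never perturbs another.

## Numerical choices and degenerate inputs

* WLS fits use statsmodels; the correction-factor regression is closed-form.
* Zero/negative IS areas raise a missing-IS error (never a silent zero);
  degenerate calibration designs (< 5 distinct levels, all-equal levels) and
  zero-variance regressions raise typed errors.
* RT ties in IS assignment break toward the earlier-eluting standard;
  rank ties use average ranks everywhere.
* Problem sizes in tests and in the acceptance script (12-level curves,
  200-replicate recovery studies, 4-sample scan-level end-to-end runs) were
  chosen as the smallest sizes at which the estimators' Monte-Carlo behaviour
  is stable.

## Known limitations

* One quantifier ion per analyte; no adduct or in-source-fragment inference,
  no deconvolution of isomers co-eluting within the integration window.
* No cross-run RT alignment or drift correction; no matrix-effect correction
  beyond IS normalization.
* 33 of 34 packaged correction factors are placeholders pending derivation
  from authentic standards; their results are flagged `unverified_factor`.
* A 12-point 1/x²-weighted slope at 5% noise is less precise than the naive
  `cv/√n` intuition suggests: error propagation gives a slope SD of 1.61%
  (only ≈94% coverage at ±3%), because the free intercept absorbs part of
  the low-level information. The test suite checks 2σ/3σ coverage against
  that closed form.
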