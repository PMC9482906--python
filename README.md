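# steroquant

Parallel **targeted + untargeted absolute quantitation of steroids** from
LC-HRMS data, for labs running multi-steroid serum/peritoneal-fluid panels.

Clinical steroid panels are usually *targeted*: only analytes with their own
isotopically labeled internal standard (IS) and calibration series can be
quantified, and the panel is frozen at acquisition time. Because full-scan
high-resolution data contains every ionizable steroid, any further compound
with a known mass and retention time can be quantified *post hoc* against the
calibration curve of a structurally related targeted analyte — a **surrogate
calibration** — once the constant ionization-efficiency difference between the
two compounds is known.

## The model

For a targeted analyte, isotope dilution gives the response ratio
`R = A_analyte / A_IS`, calibrated by weighted least squares (1/x² weighting)

```
R = a·C + b            →  C = (R − b)/a          [C in nmol/L]
```

with per-level back-calculation accuracy rules (±15%, ±20% at the LLOQ)
deciding curve acceptance and the valid range `[LLOQ, ULOQ]`.

For an untargeted analyte `u` with surrogate `s` (A4 for C19 steroids, P4 for
C21 steroids), pushing the response of `u` through the surrogate's curve gives
an *apparent* concentration `C_app` in surrogate equivalents. Because both
curves are linear over four decades, the bias is a single multiplicative
constant — the **correction factor** `f_u`, obtained by zero-intercept
weighted regression of true on apparent concentration over a matched
calibration series:

```
C_u = f_u · C_app      e.g.  f = 0.329 for 11-ketoandrostenedione vs A4
```

Around that core the package provides:

* **panel** — a 51-steroid registry (17 targeted + 34 untargeted, 13 IS),
  m/z computed from molecular formulas, nearest-RT IS assignment;
* **chromatography** — XIC extraction at a fixed 5-mmu tolerance and
  trapezoidal peak integration above a linear baseline (mzML or CSV input);
* **calibration** — `CalibrationModel` / `CorrectionFactorModel` with
  statsmodels-style `fit()` → results carrying diagnostics and `summary()`;
* **validation** — FDA-style accuracy/precision/carryover/stability rules on
  QC replicate sets (≤20% at LLOQ, ≤15% elsewhere);
* **pathways** — apparent enzyme activities (product/substrate ratios, e.g.
  CYP17A1 = 17OHP4/P4) and menstrual-cycle-phase classifier scores;
* **correlation** — Spearman matrices (exact permutation p for n ≤ 9) with
  average-linkage cluster ordering and serum-vs-PF comparison;
* **simulate** — synthetic calibration/QC/cohort/scan generators with ground
  truth, so the whole pipeline is testable without instrument data.

## Worked example

Simulate a phase-structured paired serum/PF cohort, quantify it against a
simulated calibration set, and score the phase classifiers:

```bash
steroquant run --stages simulate,quantify,classify --seed 1 --out demo/
```

`demo/concentrations.csv` holds absolute concentrations per sample — targeted
analytes through their own curves, untargeted ones through surrogate
calibration (first sample shown):

```
 sample_id  analyte  conc_nmol_per_l       mode
S001-serum cortisol       147.771893   targeted
S001-serum       P4         2.907361   targeted
S001-serum    11KA4         1.594815 untargeted
   S001-PF cortisol        69.221222   targeted
   S001-PF       P4         7.111971   targeted
   S001-PF    11KA4         0.843367 untargeted
```

Cortisol is about twice as concentrated in serum as in peritoneal fluid while
progesterone is ~2.5× enriched in PF — the matrix asymmetry the generator
encodes (adrenal steroids enter PF by transudation; progestogens are
ovary-derived). `demo/classifiers.csv` holds the phase-classifier scores; the
median combined PF classifier per phase,

```
dienogest         1.36
menstruation      8.49
proliferative     6.47
secretory        70.19
```

separates the high-progesterone secretory phase by an order of magnitude.

The validation rule engine on the packaged inter-day QC table of the
17-analyte targeted assay:

```bash
steroquant report --out validation.md        # add --paper-labels for the
                                             # swapped Accuracy/Precision headers
```

ends with `Analytes passing: 17/17` (worst LLOQ-level RSD 16.6%, worst
high-level RSD 14.9%).

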