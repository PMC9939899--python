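# Methods

## Setting

`dynrad` analyses multi-phase contrast-enhanced CT (CECT) of colorectal
liver metastases (CRLM) treated with first-line bevacizumab plus
chemotherapy. After intravenous contrast, a lesion is imaged at four
vascular phases — precontrast (PP), arterial (AP, ~30–35 s), portal
venous (PVP, ~60–75 s) and delayed (DP, ~100–120 s). Tumour vascularity
shows up as the *pattern* of enhancement across those phases, which is
why phase-to-phase change of radiomics features, rather than any
single-phase value, is the natural predictor for an antiangiogenic
endpoint.

Two endpoints are modelled:

* **best response** — objective response (OR: CR or PR under RECIST 1.1)
  versus no objective response (NOR), a binary classification;
* **progression-free survival (PFS)** — days from treatment start to
  progression or death, right-censored.

## Static features

One phase's image plus its ROI mask yields a static feature vector.
Preprocessing follows the common CT-radiomics settings: z-score
normalisation over the whole volume, scaled by 100 and shifted by
1000; resampling to 1 mm isotropic voxels (B-spline for the image,
nearest-neighbour for the mask, re-binarised at 0.5); fixed-bin-width
discretisation with width 25 anchored at the ROI minimum
(`level(v) = floor((v − min)/width) + 1`).

Three families are computed in-house:

* **first-order** — 17 statistics of the ROI intensity distribution
  (moments, percentiles, energy, histogram entropy/uniformity, ...);
* **shape** — voxel volume, exposed-face surface area, elongation and
  flatness from the eigenvalues of the voxel-coordinate covariance,
  a sphericity proxy `(36π V²)^{1/3} / A`, and the maximum 3-D diameter
  (computed over the convex hull for large ROIs);
* **GLCM** — co-occurrence texture at distance 1 over the 13 unique 3-D
  directions, symmetric accumulation, features averaged over directions
  (contrast, correlation, joint/difference entropy, IDN, IDMN, IMC1/2,
  MCC, cluster shade/prominence), following the IBSI reference
  formulas.

Run-length, size-zone, NGTDM, GLDM and filtered-image (wavelet,
exponential, square-root) families are *not* re-implemented: when they
are wanted they are ingested from the CSV output of a full external
extractor through the same feature-table reader. The package's own
contribution is the dynamic construction, and every downstream stage is
agnostic to where the static columns came from.

Degenerate inputs are surfaced, not silenced: a constant volume cannot
be z-scored (error); a single-voxel ROI yields NaN with a recorded
reason for shape anisotropy and GLCM features; a GLCM with a single
occupied gray level reports correlation 1 and IMC 0 by convention.
Features constant across the cohort (range < 1e−12) are dropped with a
logged count before analysis.

## Dynamic features

A static feature tracked over the k ordered phases is a short series
f₁..f_k with mean f̄. Five transforms turn it into dynamic features:

| kind | definition | count (k=4) |
|------|------------|-------------|
| SD   | (1/k) Σᵢ \|fᵢ − f̄\| | 1 |
| DC   | SD / \|f̄\| | 1 |
| RCR  | \|fⱼ − fᵢ\| / \|fᵢ\|, j < i | 6 |
| RACR | \|fⱼ − fᵢ\| / \|f̄\|, j < i | 6 |
| P    | OLS coefficients of fᵢ on {1, t, …, t^d} | d + 1 |

Conventions where the definitions leave room:

* **Pair range.** The pair index range is taken as j < i; the j = i
  diagonal is identically zero and would be removed as constant anyway.
* **Denominator sign.** Radiomics features can be negative (skewness,
  cluster shade), so denominators are taken in absolute value; every
  dynamic feature is a nonnegative magnitude. This is recorded in the
  column metadata.
* **RCR denominator phase.** The *later* phase of the pair divides by
  default; a `rcr_denominator="earlier"` switch provides the
  baseline-normalised variant, since either convention is defensible.
* **Mean interpretation.** f̄ is the mean of the feature values across
  phases (not the feature of a mean image).
* **ε-guard.** |denominator| < 1e−12 yields 0 and a flag instead of
  Inf/NaN, keeping matrices finite for selection.
* **Phase times.** Ordinal times (1, 2, 3, 4) by default; a
  nominal-seconds mode (0, 32.5, 67.5, 110 — midpoints of the
  acquisition windows) is available. Only the polynomial transform uses
  times; the other four are time-agnostic.
* **Polynomial degree.** Default d = k − 1 (4 coefficients for 4
  phases, an interpolating fit with zero residual); lower degrees give
  smoothed trends with a reported residual sum of squares.

Column names are deterministic (`<base>__RCR_1to2`, `<base>__P_a0`, …)
and each column carries provenance (base feature, transform kind, phase
pair or coefficient index, ε-guard flag).

## Feature screening and response models

Screening is two-stage, in this order: a per-column Welch two-sided
t-test between OR and NOR keeps p ≤ 0.05 (no multiplicity correction —
the screen is a filter, not an inference); then an L1-penalised
logistic regression on the standardised survivors, with the penalty
chosen by stratified 5-fold inner-CV deviance over a fixed grid of nine
values log-spaced in C ∈ [10⁻², 10²] (liblinear). Nonzero coefficients
at the chosen penalty define the kept set. Columns where both groups
have zero variance get p = 1 (equal means) or p = 0 (perfect
separation) instead of NaN. If nothing survives, models fall back to
the single strongest t-filter column, flagged.

Evaluation is leave-one-out: each patient is scored by a model trained
on the other n − 1, and the pooled held-out scores give one ROC per
(feature set, classifier) cell — the only coherent ROC for LOOCV.
Feature sets compared: the five dynamic kinds, each single phase's
static features, and their concatenation (`Multi_static`). Classifiers
(hyperparameters are deliberately plain, since nothing in the protocol
motivates tuning): LDA with `lsqr` + automatic shrinkage (the pooled
covariance is usually singular when p > n), linear-kernel SVM at C = 1
scored by decision value (threshold 0), and a 500-tree random forest
with √p features per split scored by class probability (threshold 0.5).

**Selection placement.** By default (`onepass_selection=False`) the
full screen is refit inside every LOOCV training fold, which is the
leakage-free protocol. `onepass_selection=True` selects once on the
complete data before LOOCV; on null data this variant is optimistically biased,
and the test suite asserts the *direction* of that gap rather than
pretending either mode reproduces any particular published cell. Which
placement produced the published comparison tables cannot be determined
from the protocol text, so both are provided and labelled.

## Survival workflow

The winning dynamic set (RCR by default) feeds a four-step PFS
pipeline:

1. **Univariate Cox screen** per feature (Efron ties, Newton–Raphson
   via lifelines; features standardised so betas are per-SD), keeping
   Wald p < 0.05; constant or non-converging columns are excluded with
   a flag. If nothing passes, the smallest-p feature is used, logged.
2. **Random survival forest risk score** — log-rank splitting, √p
   candidate features, minimum leaf size 3, 500 trees by default; the
   score is the ensemble cumulative hazard summed over the event-time
   grid. With `loocv=True` (default) each patient's score comes from a
   forest grown without them; the full-fit variant exists behind the
   same switch because the published description of the combination is
   ambiguous.
3. **Median split** into high/low risk (ties at the median go low, a
   deterministic rule), compared by Kaplan–Meier curves and the
   two-group log-rank test.
4. **Time-dependent ROC** at 90/180/270/360 days: the
   cumulative-case/dynamic-control estimator with Kaplan–Meier
   censoring handling (sensitivity and specificity at each threshold
   from the overall KM curve and the KM curve of the above-threshold
   subgroup via Bayes' theorem, AUC by trapezoid). Without censoring
   this reduces exactly to the empirical ROC of "event by t". The
   smoothed nearest-neighbour variant is not implemented.

Harrell's C of the risk score is reported as a diagnostic.

## Baseline statistics

`fisher_exact_2x2` / `fisher_exact_rxc` enumerate all tables with the
observed margins (log-space hypergeometric probabilities) and sum those
at most as probable as the observed table, with a 1e−7 relative slack
on the comparison to absorb float noise. All-zero rows/columns are
removed first; a table that degenerates to a single row or column has
p = 1. The r×c enumeration is exact and guarded by a table-total limit
of 10⁴ and an enumeration budget.

A practical finding the package documents and tests: the published
76-patient baseline table that serves as the worked example footnotes
Fisher's exact test, but its printed p-values are reproduced (to the
printed 3 decimals) by *chi-square* tests — Yates-corrected for the
2×2 rows (sex 0.323, CEA 0.671, AFP 1.000, age ≤55/>55 0.629) and
plain Pearson for the 3×2 tumour-site row (0.597). The correct Fisher
values on the same counts are 0.253, 0.490, 1.000, 0.610 and 0.650
(verified against independent references). `table2_report` therefore
prints both columns. Tumour size is continuous and is summarised as
mean (SD) with Student and Welch t-tests; no count-based exact test
applies, and no claim is made about which test produced the published
0.165.

## Synthetic cohort generator

The study's imaging data are private, so the generator defines the
conditions under which the pipeline is exercised. For an informative
feature f of patient i at phase p:

    f_ipf = m_f · b_if · e_g(p) · exp(ε),   ε ~ N(0, noise_sd²)

* `m_f ~ 10^U(0,3)` — feature scales span three decades, as radiomics
  feature families do;
* `b_if = exp(N(0, baseline_sd²))`, baseline_sd = 0.6 — between-patient
  heterogeneity that dominates single-phase variance but cancels
  exactly in phase ratios; this is the mechanism that makes dynamic
  features outperform static ones *by construction*, which is the
  qualitative claim the cohort is built to probe;
* `e_g(p)` — enhancement curves normalised to mean 1 across phases
  (so the phase-averaged level is matched between groups): shared
  profile (1, 1.8, 1.6, 1.3)/mean for NOR, and for OR the profile
  interpolated `effect_size` of the way towards the flatter
  (1, 1.25, 1.2, 1.1)/mean. `effect_size = 0` is an exact null;
* `noise_sd = 0.1` — per-phase multiplicative log-normal measurement
  noise (an additive-Gaussian alternative is a config switch).

Noise defaults are the implementer's choice — the source protocol
reports no feature-scale distributions — and are documented here, not
claimed as literature-derived. Defaults mirror the study frame where it
is stated: 76 patients, 33/76 OR fraction.

PFS follows a proportional-hazards Weibull (shape 1.5, scale 300 days)
whose log-hazard is `pfs_coef` times the standardised per-patient
PP→AP log-ratio signal over informative features, so the survival
signal flows through the same dynamic structure the classifier sees.
Censoring is independent uniform on [0, m] with m calibrated by
bisection to the requested censor fraction (default 0.2). With
`pfs_coef = 0` and no censoring the KM median matches the analytic
Weibull median `scale · (ln 2)^{1/shape}`.

Clinical covariates (age, sex, site, tumour size, CEA, AFP) are drawn
independent of outcome, consistent with a baseline table in which no
covariate separates the groups.

Voxel-level phantoms (ellipsoidal lesion on a uniform liver background,
lesion mean tracking the enhancement curve, additive Gaussian noise)
exercise the image→feature path end to end.

**What the generator does not emulate:** scanner/batch effects,
spatial texture structure within lesions (phantom lesions are uniform),
correlated feature blocks, segmentation variability, or informative
censoring. Passing tests therefore demonstrate the *machinery* —
transforms, leakage-free evaluation, calibration under the null, power
under a known signal — not clinical performance on real CRLM data, and
no numeric cell of the published comparison tables is claimed to be
reproduced (the cohort is private).

## Problem sizes used by the test suite and acceptance script

Chosen to keep a full run on one CPU comfortable while leaving every
statistical check well-powered:

* null calibration: 20 cohorts (tests) / 10 (script) of n = 60, 50 base
  features → 300 RCR columns;
* signal recovery: 10 cohorts (tests) / 5 (script) of n = 80 (script:
  n = 76), 200 base features, 20 informative, effect size 1.0;
* survival: forest of 100 trees in tests and script (500 is the
  library default; with the strong simulated signal the score ranking
  is already stable at 100), leave-one-out scoring, 5–10 cohorts of
  n = 80;
* GLCM oracle: 50 random ROIs of up to 6³ voxels;
* Fisher oracle: exhaustive 2×2 totals ≤ 16 plus 300 random larger
  tables.

## Known limitations

* GLRLM/GLSZM/NGTDM/GLDM/wavelet static families only via external
  tables; no 2-D extraction mode; no LoG/exponential/square-root image
  filters.
* No nomogram or calibration-curve graphics; no multivariable Cox; no
  competing risks.
* The r×c exact test enumerates completely — fine for baseline-table
  sizes, not for large sparse tables (no Monte-Carlo fallback).
* MRML scene files are not parsed; masks must arrive as NRRD or
  arrays.
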