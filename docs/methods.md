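# Methods

## Analysis unit and data model

The unit of analysis is one reader's description of one peripheral-zone
lesion, matched to prostatectomy pathology.  Lesions are clustered
within patients, and a patient can contribute several lesions; every
inferential procedure in the package treats the *patient* as the
exchangeable unit.  Readers are independent strata end to end — a
cohort is always analysed one reader at a time, never pooled.

A record carries the per-sequence ordinal signal scores (0 not visible,
1 mild, 2 moderate, 3 marked on T2W, DW and DCE), per-sequence volumes
(present exactly when the lesion is visible on that sequence — a
delineated lesion always yields a volume, so the visibility/volume link
is an iff), one resolved shape category, an ECE score 1–5, a Likert
score 2–5 (a score of 1 is reserved for normal-appearing tissue, so a
recorded focal lesion scores at least 2), patient-level PSA density,
and the outcome: ISUP grade group 0 (benign) to 5 plus a lesion-level
histological EPE flag.  EPE is mandatory and fixed false for benign
findings, avoiding a three-valued field.  Records flagged as excluded
(e.g. DW artefacts) are retained in storage and dropped at analysis
entry, so pre- and post-exclusion counts both remain reportable.

Three nested-by-construction outcome definitions are supported:
csPCa-A (grade group ≥ 2), csPCa-B (grade group ≥ 3) and csPCa-C
(grade group ≥ 2 with EPE).  B- and C-positives are subsets of
A-positives on any cohort.

## Derived features and the model battery

S_Max counts the sequences showing a marked (3/3) abnormality over a
chosen sequence set; S_Min flags invisibility (0/3) on at least one
sequence, dichotomized 0 vs ≥ 1; V_Max is the largest per-sequence
volume; shape is grouped to six levels by merging ill-defined areas
with linear-perpendicular lesions.  Sequence sets: variant "a" uses
{T2W, DW, DCE}; variant "b" drops DCE.  The Signal2 models code DW
separately, so their starred S_Max/S_Min run over {T2W, DCE} (2a) or
{T2W} (2b), with the same "marked"/"not visible" thresholds.

The battery is fixed, not selected: nine univariable models (defined on
the full sequence set only), S_Max alone, Signal1 = S_Max + S_Min,
Signal2 = S_Max* + S_Min* + S_DW, Signal3 = the raw per-sequence
scores, and Signal1 plus each of the 15 non-empty subsets of
{Shape, ECE, V_Max, dPSA} — 28 specifications with DCE, 19 without.

Ordinal predictors enter as unordered indicator contrasts against the
lowest observed level.  This is deliberately assumption-light: it never
imposes linearity on a subjective 4- or 5-level scale, at the price of
more parameters.  A config switch (`ordinal_as_linear`) provides linear
scoring for sensitivity analysis.  V_Max and dPSA enter untransformed
by default.  Categorical levels observed fewer than 3 times (config:
`min_level_count`) are merged toward the reference level, with a logged
warning — small cohorts otherwise produce empty-cell separation in
nearly every bootstrap replicate.

Fitting is plain maximum likelihood (statsmodels `Logit`).  If the fit
fails to converge, separates (any |coefficient| ≥ 30) or yields
non-finite estimates, the model is refit with a small L2 penalty
(strength 1e-4 on standardized columns) and flagged; coefficients stay
finite and every lesion still gets a probability.  Columns constant in
a given sample — e.g. a categorical level absent from a bootstrap
replicate — are dropped for that fit and get coefficient 0, which is
equivalent to merging the unseen level into the reference when scoring
other data.

## AUC, optimism correction and inference

The AUC is the Mann-Whitney estimator with ties counted 1/2, computed
from average ranks; it equals exhaustive enumeration over
positive × negative pairs exactly (property-tested).

Because each model is fit and evaluated on the same lesions, the
apparent AUC is optimistic.  The bootstrap correction refits the model
on replicates drawn by resampling patients with replacement (a drawn
patient contributes all their lesions; repeat draws get distinct
synthetic cluster ids) and estimates

    optimism_b  = AUC(fit_b on replicate_b) − AUC(fit_b on original)
    corrected   = apparent − mean_b(optimism_b)

Replicates whose resampled outcome is single-class are skipped and
counted, never redrawn — redrawing would bias the resampling
distribution.  `B` defaults to 1000 and is configurable; the heavier
simulation checks in this repository use 200–500.

Confidence intervals reuse the same replicate stream.  The interval is
the 2.5–97.5 percentile range of the replicate *apparent* AUCs (each
replicate fit scored on its own bootstrap sample), shifted to be
centred on the corrected estimate; a "basic" interval (reflection
around the point estimate) is a config switch.  The replicate
out-of-sample AUCs were considered and rejected as the interval basis:
their spread reflects only refit variability on a fixed evaluation set
and collapses for stable models, far below the sampling variability an
AUC interval must carry.

Paired comparison of two models fits both on every replicate of one
shared stream and uses Δ_b = AUC_orig(a) − AUC_orig(b): on the common,
fixed evaluation set the paired difference is the meaningful quantity,
and correlated evaluation noise cancels.  The point estimate is the
difference of corrected AUCs; the two-sided p-value is the
recentred-null position of zero, p = 2·min(F̂(0), 1−F̂(0)) with ties at
zero counted on both sides (so a self-comparison gives Δ = 0, p = 1
exactly).  The Likert baseline uses the 2–5 score directly as the
ranking — no fit, zero optimism by construction — with a clustered
bootstrap percentile interval; a model-vs-Likert comparison treats the
Likert AUC as fixed within each replicate's evaluation.  No multiplicity
adjustment is applied across the battery grid.

## The synthetic cohort generator

The generator emulates the data structure the analysis assumes, not any
particular patient.  Per patient: a lesion count from a zero-truncated
Poisson (mean 1.8 lesions per lesion-bearing patient) and a lognormal
PSA density (median 0.16, log-sd 0.5, matching a typical pre-biopsy
distribution).  Per lesion: a pathology class from
(benign, GG1…GG5) = (0.400, 0.168, 0.214, 0.100, 0.070, 0.048), chosen
so the marginal prevalences sit near a prostatectomy series — csPCa-A
43%, csPCa-B 22%, csPCa-C 21%, EPE ≈ 22–23%.  Each ordinal signal
score follows a cumulative-logit model whose latent is a grade-group
effect (DW largest: betas 0.7/1.1/0.8 for T2W/DW/DCE, shared cutpoints
−1.0/0.3/2.2) plus standard-logistic noise; a lesion invisible on all
three sequences is redrawn, since an undetected lesion would not be in
the database.  Volumes are lognormal with a grade-group trend in the
log-mean and per-sequence jitter, masked by visibility.  EPE is
logistic in grade group and log-volume (benign lesions never carry it);
ECE is cumulative-logit in EPE and grade group; shape is class-
conditional categorical with deliberately weak separation.  The Likert
score is an ordered cut of a weighted sum of the *generated* features
(marked-sequence count, invisibility, log V_Max, ECE, log dPSA) plus
independent Gaussian reader noise — so the synthetic Likert baseline is
beatable-or-matchable by the feature models rather than hard-coded to
win or lose.  A second reader is simulated as an independent draw with
its own parameters, never by pooling.

All probability vectors must sum to 1, cutpoints must increase, and a
seed fully determines the cohort (two runs with equal parameters are
byte-identical on disk).

The *null* variant keeps the outcome side (class frequencies, the EPE
grade-group slope) and severs every feature-outcome link: score betas,
the volume trend, the EPE volume slope and the ECE effects are zeroed
and shape becomes class-independent.  Any discrimination a model shows
on a null cohort is pure overfitting, and any feature's true
out-of-sample AUC is 0.5 exactly by independence — the calibration
fixture for the optimism machinery.

What the generator does *not* emulate: images or reader psychology,
inter-reader correlation, scanner field strength, outcome correlation
within a patient beyond the shared PSA density, or the exact per-class
score distributions of any real cohort (which are not publicly
available).  Passing tests therefore demonstrate that the statistical
machinery is correct and calibrated under a realistic data structure,
not that the synthetic effect sizes match clinical reality — the
generator's discrimination (corrected AUCs near 0.89 for the best
models) runs higher than a typical clinical series.

## Problem sizes and numerical choices

The simulation-based checks use: null calibration at 200 patients,
B = 500, 20 seeds; parameter recovery at 250 patients, B = 200, 20
seeds against an independent ~10^5-lesion test cohort; noise-covariate
comparisons at 250 patients, B = 200, 20 seeds — sizes chosen to keep
Monte-Carlo error well inside the asserted tolerances while the whole
suite remains desk-scale.  Bootstrap seeds are derived per cell from a
base seed by CRC hashing, so every cell is independently reproducible
and results are exactly invariant to the lesion order of the input
(the analysis frame is canonically sorted on entry).

## Known limitations

* The standard refit-on-replicate optimism estimate under-corrects for
  richly parameterized models on small clustered cohorts: the replicate
  model is evaluated on the original sample, ~63% of whose patients were
  in its training set.  On null cohorts of 200 patients the full
  Signal1+Shape+ECE+Vmax+dPSA model (≈15 design columns) retains a mean
  corrected AUC of ≈ 0.53 rather than 0.50, while lean models (Signal1,
  4 columns) calibrate to ≈ 0.503.  This residual optimism is a known
  small-sample property of the estimator, consistent with published
  studies of bootstrap-validated concordance indices; corrected AUCs of
  the largest models on small cohorts should be read as upper-ish
  bounds.
* Prevalence denominators follow whatever records are evaluable; the
  package does not model per-definition denominator discrepancies that
  can arise from upstream data handling.
* No DeLong analytic comparison, cross-validation alternative or
  calibration metrics; the bootstrap machinery is the single inference
  route by design.
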