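# Methods

This note documents the models implemented in `infersens`, the assumptions
behind the synthetic cohort generator, the estimators used for accuracy and
agreement, and the design decisions taken where the problem left room.

## 1. Synthetic structure–function cohorts (`simulate`)

### Stimulus grid

The perimetry pattern has 50 points centred on the fovea, dominated by a
horizontal-meridian profile: 13 loci every 2° from temporal 14° to nasal 10°
(negative x = temporal). Off-meridian rows complete the pattern: the same 13
x-positions at y = ±2°, six points (x = −12…+8, every 4°) at y = +4° and five
(x = −10…+6) at y = −4°. Only the meridian loci are constrained by the
feature-set definitions (the 7- and 13-point seed subsets); the off-meridian
layout is a free choice and validated only for uniqueness and completeness of
the required meridian loci.

### Retinal architecture

Five layers are modelled: full retina (FR, ILM→Bruch's membrane), inner
retina (IR), outer nuclear layer (ONL, including Henle fibres), photoreceptor
inner/outer segments (IS&OS, ELM→band 3) and RPE (band 3→BrM). Normative
thickness is a smooth function of eccentricity r (ONL/IS&OS peak foveally, IR
is thinnest at the fovea) plus a linear age effect (e.g. ONL −0.15 µm/yr,
referenced to age 40), patient and eye random intercepts, and white per-point
residual (e.g. IS&OS: SD 3.0/1.4/1.5 µm for patient/eye/residual). Each
layer carries a mean reflectivity level (arbitrary units) with its own small
random effects.

Disease severity s ∈ [0, 1] (Beta(2,2) across patients, multiplicative
between-eye asymmetry, linear progression over visits at 0.04/yr) thins the
outer layers by a fraction `depth_l · s · exp(−(r/8°)²)` — strongest at the
fovea, with maximal foveal depths 0.92 (IS&OS), 0.75 (RPE), 0.55 (ONL), 0.30
(FR), 0.05 (IR) — and darkens IS&OS/RPE reflectivity. A per-eye, per-layer
lognormal expression multiplier (log-SD 0.3) prevents the layers from
thinning in lockstep: without it, layer involvement is perfectly collinear
and no importance method could distinguish the causal layers from proxies.
Within an eye, random effects and residual fields are drawn once; across
visits only disease progression (and not normal aging, which is negligible
over follow-up intervals) alters true structure, so zero progression
reproduces baseline structure exactly.

En-face maps are produced the same way real ones are: a synthetic per-layer
reflectivity volume (3.87 µm axial pitch, 0.4°/pixel lattice over ±16°,
voxel scatter 25% of layer reflectivity) is projected by `enface.project_layer`
into thickness and min/mean/max intensity maps, then sampled at each stimulus
with the 0.43° Goldmann-III aperture. The feature path in the pipeline is
therefore the same code the en-face unit tests verify against a per-pixel
oracle.

### Ground-truth structure→function map

True threshold at a locus is

    T = S₀(r, age) − L( Σ_l w_l · max(0, −z_l) ) + offset + ε,   clamped to [0, 36] dB

with S₀ the normative sensitivity surface (28 dB foveal, −0.18 dB/°,
−0.05 dB/yr), z_l the true layer-thickness z-scores, weights
w = (IS&OS 6, RPE 4, ONL 1.2, FR 0.8, IR 0.3) dB per z-unit — IS&OS ≥ RPE >
others by construction, so importance analyses have a known recoverable
ranking — and L a saturating link `knee·tanh(u/knee)` (knee 30 dB; a linear
link is available). ε is per-point biological scatter (SD 2 dB).

`offset` is an eye/session-level functional shift (SD 3.5 dB) shared by all
points of one test session: response criterion, fatigue and adaptation move
a whole test up or down in a way retinal structure cannot explain. Part of it
is predictable from the performance covariates (−6.0 dB per log-unit of
fixation-instability noise, −6.5 dB per logMAR of acuity noise; ≈1.8 dB of
the 3.5 dB SD), the rest is latent. This component is what makes brief-test
feature-sets (4/5) genuinely more accurate than imaging + covariates (3),
and covariates more accurate than imaging alone — the central qualitative
relationship the pipeline is designed to exhibit.

### Measurement model: 4–2 staircase

Thresholds are measured by a yes/no staircase over a 36 dB (3.6 log-unit)
dynamic range: start 10 dB below ceiling, 4 dB steps to the first reversal,
2 dB steps to the second, threshold = last seen level; "not seen" at the
brightest stimulus codes as 0 dB (keeping targets numeric). Responses follow
a logistic psychometric function (spread σ = 3 dB) with 1% guess and
lapse rates. With σ → 0 the procedure is deterministic and lands within 2 dB
of the true threshold everywhere inside the range (verified by enumeration).
σ = 3 dB was calibrated once, by Monte-Carlo over thresholds 2–30 dB, to
place the intra-session retest mean |difference| at ≈3.5 dB, the regime
reported for mesopic microperimetry in macular dystrophy; it was frozen
before any acceptance measurement.

### What the generator does not emulate

No B-scan imagery or segmentation errors (boundaries are exact), no fixation
drift or registration error (coordinates are exact; a no-op registration hook
marks where it would go), no floor-induced censoring structure beyond the
clamp, no spatial correlation in the residual fields beyond the smooth
disease/normative surfaces, and no device- or operator-specific effects.
Passing tests therefore demonstrate that the *pipeline* recovers known
structure under its stated assumptions — not that those assumptions hold for
any particular instrument or clinic population.

## 2. Normative standardization (`standardize`)

Per (location, variable): statsmodels `MixedLM`, value ~ age with a patient
random intercept and an eye-in-patient variance component, REML/L-BFGS.
SD_normative is the total SD √(σ²_patient + σ²_eye + σ²_resid) — z-scores
express deviation relative to between-subject normal variability, which is
what "normative SD" bands on contribution plots should mean. Singular or
non-converged fits fall back to OLS with pooled residual SD under a logged
warning. Normative means are evaluated, by default, at one fixed reference
age (the patient cohort's median); a per-subject-age policy is provided
because either reading of "median age as reference" is defensible, and the
choice shifts all z-scores by a small age-dependent amount without affecting
model comparisons.

## 3. Feature-sets and null models (`featuresets`)

Sets 1–3 stack imaging z-scores, reliability indices and covariates (ERG
group and onset category enter as ordered integers — both are ordinal
severity scales and forests are invariant to monotone recoding). Sets 4/5
append the measured loss at the 7 or 13 seed loci (taken from the first test
of each session, broadcast within eye × visit) and one-hot eye indicators
defined over the full dataset (held-out eyes' columns are constant zero in
training — implemented literally; the forest cannot exploit unseen IDs).
Seed-locus rows are excluded from the evaluation mask, and
`FeatureMatrix.assert_no_leakage()` verifies programmatically that no scored
row carries its own measurement among its predictors. Null models predict
the training-set mean loss (sets 1–3) or each test eye's mean over its 13
every-2° loci (sets 4/5).

## 4. Forest and nested cross-validation (`model`)

The forest is explicit bagging over scikit-learn regression trees with `mtry`
(`max_features`) candidate predictors per split and `min_samples_leaf = 5`;
per-tree bootstrap and out-of-bag indices are retained because both the
%IncMSE convention and contribution walks need them. `n_trees` defaults to
500 (configurable; tests and desk-scale runs use 8–100). Accuracy comes from
nested resampling: 5 outer patient-wise folds; within each outer training
set, 5 inner patient-wise folds select `mtry` by minimal inner MAE (MAE for
consistency with the reported metric; smallest value wins ties); the tuned
forest refits on the outer training set and predicts the outer fold's
evaluation rows. All of it repeats over a seed list (default 7) and metrics
are computed per seed, then averaged — not on pooled predictions. Grid values
above p are clamped to p (relevant on small synthetic cohorts where
p < 120); folds whose evaluation rows would be empty trigger a logged
re-split with a seed offset.

## 5. Error and agreement estimation (`evaluate`)

MAE/RMSE are estimated per seed by an intercept-only mixed model on the
per-point absolute (squared) errors with nested random intercepts
patient ⊃ eye ⊃ visit; the intercept is the estimate (RMSE via square root
with a delta-method CI), its Wald interval the within-seed CI. Across seeds,
the point estimate is the mean and the combined variance adds the mean
within-seed variance and the between-seed variance (×(1+1/S)). Grouping
levels without replication are dropped; a fit whose intercept leaves the span
of the patient-level means (a symptom of a degenerate optimum on tiny data)
is rejected in favour of the next simpler model, ending at the grand mean
with patient-cluster-robust SE. On balanced single-visit data the estimator
agrees with the pooled mean to well under 1%.

Bland–Altman agreement uses the same intercept model for the mean difference;
limits of agreement are mean ± 1.96 × total SD (variance components +
residual), with a MOVER-style approximation for the LoA intervals
(SE²_LoA = SE²_mean + 1.96²·SE²_SD, SD uncertainty from the number of eye
clusters). Prediction-vs-observation mode scores predictions against each
test run separately — the conservative pairing.

ETDRS subfields use ring diameters 1/3/6 mm converted at 291 µm/° (central
< 1.72°, inner < 5.15°, outer < 10.31° radius; beyond that, nasal/temporal
periphery by the sign of x, with x = 0 counting as nasal). The same constant
relates the 0.43° aperture to µm-pitch maps.

## 6. Importance and contributions (`importance`)

%IncMSE is per-tree out-of-bag permutation: permute one feature's column
within a tree's OOB rows and compare MSEs,
`100·mean_t(MSE_perm − MSE_oob)/mean_t(MSE_oob)`; a constant column has
importance 0 by definition. Importance is computed on outer-fold training
forests and medians pooled across seeds × folds. Contributions walk each
tree root→leaf crediting every split's change in node mean to the split
feature; baseline + Σ contributions equals the forest prediction exactly
(telescoping), which the tests assert to 1e−6. The goodness-of-visualization
R² smooths contribution vs feature value by lowess; span 0.3 (small enough
that a noiseless smooth relationship scores > 0.99, the defining property;
larger spans visibly underfit curvature).

## 7. Problem sizes

Generator defaults mirror the emulated study design (134 patients × 2 eyes,
54 controls, 50 points, 0–36 dB). The test-suite and acceptance script use
scaled replicas chosen as the smallest cohorts at which the qualitative
results are stable: acceptance runs 24 patients × 2 eyes × 50 points against
16 controls with 60 trees and 2 CV seeds (7 seeds × 2 folds for importance),
plus a 16-patient retest cohort; the analysis drivers use 16/12 patients and
40 trees. At these sizes a full acceptance run takes a few minutes on one
CPU.

## 8. Known limitations

* The mixed-model CIs are Wald intervals; at very small cohort sizes they
  can be anticonservative, and the seed-combination rule is heuristic.
* mtry grids {120, 160, 200} collapse to {p} on cohorts with few eyes, so
  sets 4/5 run as bagged trees there; tuning behaviour at the emulated
  study's scale (p ≈ 300) is exercised only if larger cohorts are generated.
* The staircase model omits inter-trial dependencies (no fatigue drift within
  a test) and the fixed 1% guess/lapse rates are not fitted per subject.
* Feature contributions follow the node-mean decomposition; they are not
  Shapley values and shared credit between correlated features is
  split-order dependent.
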