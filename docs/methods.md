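# Methods

`rusfresp` implements a host-microbiome analysis of growth response to an
8-week course of ready-to-use supplemental food (RUSF) in acutely
malnourished infants. It covers two analysis arms — a serum/urine/fecal
biomarker arm and a fecal 16S amplicon (ASV) arm — plus the anthropometric
machinery that defines the response phenotype, and a synthetic-cohort
generator that reproduces the statistical structure of such a study with
known ground truth.

## Response phenotype and anthropometry

Growth is expressed as WHO z-scores: weight-for-age (WAZ), weight-for-length
(WLZ), length-for-age (LAZ). The package consumes z-scores; conversion from
raw weight/length against the WHO reference is out of scope.

Nutritional status uses the standard cut-offs: stunted LAZ < −2, underweight
WAZ < −2, at risk of wasting −2 ≤ WLZ < −1, moderate wasting −3 ≤ WLZ < −2,
severe wasting WLZ < −3. The inequalities are read strictly, so WLZ exactly
−2 is at-risk and exactly −3 is moderate; the wasting categories partition
the WLZ axis.

Response to RUSF is weight-for-age velocity (ΔWAZ/month) over the
intervention window (9–11 months of age), computed between the visits
nearest the window endpoints (±0.5 month tolerance). Velocity > 0.5/month
labels a responder, ≤ 0/month a nonresponder, anything between is
intermediate; both thresholds are configurable. A parent-study criterion
(WLZ ≥ −2 one week post-intervention) is available separately. Dosing
arithmetic follows the field protocol: one sachet daily for moderate
wasting, weight-based dosing (200 kcal/kg/day, rounded up to whole sachets,
default 520 kcal/sachet) for severe wasting; compliance is percent of
distributed sachets consumed.

## Biomarker arm

Tables are complete-case filtered in two passes: markers missing in more
than 20% of samples are dropped, then samples missing more than 10% of the
surviving markers, then any residual incomplete row. Both thresholds are
parameters; the marker-then-sample order is a documented choice (the
reverse order is equally defensible but changes nothing at the default
missingness levels the generator plants).

Screening uses two-sided Wilcoxon rank-sum tests (exact null when both
groups have ≤ 10 observations and no ties; tie-corrected normal
approximation otherwise) with Benjamini-Hochberg correction across the
screened features, Pearson χ² without continuity correction for categorical
contrasts, and PCA via SVD on centered (and, for biomarkers, unit-variance
scaled) data with a deterministic sign convention: the largest-magnitude
loading of each component is positive.

The predictive-modeling procedure is an ensemble of random forests over a
leave-out partition: the n samples are split into k = 20 disjoint held-out
blocks, one forest (1,000 trees, Gini impurity, mtry = ⌊√p⌋ features per
split) is fit per block on the ~95% complement, and mean-decrease-in-Gini
importances and out-of-bag errors are recorded per iteration and aggregated
as mean ± sd per feature. mtry = ⌊√n⌋ is available behind a switch. The top
9 features by mean importance (ties broken lexicographically, so ranking is
deterministic) feed a ridge-penalized logistic regression evaluated on a
stratified 70:30 split at a 0.5 probability cut-off; a small L2 penalty
keeps the fit convergent under perfect separation.

Inflamed-outlier flagging is a deterministic surrogate for what is usually
a visual call on a PCA plot: a nonresponder is flagged when both its
composite inflammation score (mean z-score over CRP, AGP, IL-6, TNF-α,
IFN-γ, IL-1β, standardized against the control group) and its Euclidean
distance from the control centroid in the first two PCA components exceed
the 95th percentile of the controls. The marker set and percentile are
configuration; controls and responders are never flagged by construction.

## Microbiome arm

Counts stay integer; proportions are computed on demand and never stored in
the count table. Alpha diversity is observed richness and the Gini-Simpson
index 1 − Σpᵢ² (the "Simpson" convention of the common R tooling; the
inverse-Simpson variant is deliberately not the default). Beta diversity is
Bray-Curtis on raw counts, with no rarefaction: sequencing depths in the
emulated design sit on the detection plateau (~60,000 reads), where
rarefaction would only discard information.

NMDS minimizes Kruskal stress-1 by alternating isotonic regression of
configuration distances on dissimilarity ranks with a Guttman-transform
update, initialized from classical metric scaling. Iteration stops when
stress fails to improve by 1e−6 or at 500 iterations, so the recorded
stress path is non-increasing by construction. PERMANOVA computes the
pseudo-F from the standard pairwise squared-distance decomposition and a
label-permutation p-value with the (1 + count)/(1 + n_perm) convention, so
p is never zero; permuted statistics are compared against the observed one
with a 1e−9 relative tie tolerance so permutations that recreate the
observed grouping count as ties rather than being lost to summation-order
rounding. PERMANOVA runs on distances from counts by default; the
dissimilarity input is explicit, so proportion-based distances are one call
away.

Taxon aggregation sums ASVs sharing a rank label (unmapped ASVs pool under
"unassigned") with deterministic column order, and commutes with
normalization to machine precision. The cross-cohort transfer
representation concatenates percent composition at phylum, class and family
into one matrix with rank-prefixed column names, each rank block summing to
100 per sample. Correlation edges recover features that L1 selection hides:
Pearson (optionally Spearman) correlation of each model-selected anchor
against all other features, emitting |r| > 0.7 edges.

## LASSO-regularized OPLS-DA

The classifier at the core of the microbiome arm has two stages.

Selection: L1-penalized least squares of the centered ±1-encoded class on
column-standardized features, over a 30-point log-spaced λ grid from
λ_max = max|Xᵀy|/n down three decades. λ is chosen at minimum 5-fold
cross-validated squared error; if that λ selects nothing, the largest λ
with a nonempty support is used. Least-squares rather than logistic loss is
intentional: the stage exists to pick features, not to calibrate
probabilities, and the quadratic path is fast and deterministic.

Fit: the class vector y is encoded ±1 and centered; per orthogonal
component, w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/(tᵀt),
w_o ∝ p − (wᵀp)w, t_o = Xw_o, p_o = Xᵀt_o/(t_oᵀt_o), and X is deflated by
t_o p_oᵀ. After n_ortho deflations (default 1, giving the familiar
LV1/LV2 score plane) the final predictive triplet (w, t, p) and y-loading
c = yᵀt/(tᵀt) are computed. Because w ∝ Xᵀy, every orthogonal score
satisfies t_oᵀy = 0 exactly (checked to 1e−8 relative); with n_ortho = 0
the fit coincides with one-component PLS regression, which is the
equivalence oracle used in the tests. If the orthogonal weight is
numerically zero (a single feature, or X fully predictive) the model is
stored with fewer orthogonal components and a warning. Biomarker inputs
are auto-scaled (unit variance); composition inputs are centered only,
since proportions share a scale.

Prediction applies the training scaling, removes each stored orthogonal
component sequentially, and thresholds the decision score c·(Xw) at zero; a
score of exactly zero goes to the class encoded +1 (a measure-zero
tie-break, documented rather than randomized).

VIP scores use the single-predictive-component form
VIPⱼ = √m·|wⱼ|/‖w‖ over the m selected features, so the mean squared VIP is
exactly 1 and values above 1 mark above-average influence. Each score
carries the sign of the corresponding predictive loading, orienting the
feature toward the class it associates with.

Repeated cross-validation runs stratified k-fold (default 5) with a fresh
fold assignment per repetition. With nested selection (the default) the
LASSO step reruns inside every training fold, so feature selection never
sees held-out samples; the non-nested mode selects once on the full data
before the folds are cut, reproducing the likelier behavior of older
single-pass pipelines. Both modes are first-class and both are exercised.

The permutation test shuffles class labels (sizes preserved) and reruns the
full pipeline — selection, fit, and an inner CV at reduced repetitions
(default 10) — per permutation; p = (1 + #{permuted ≥ observed})/(1 +
n_perm). The observed accuracy is computed with the same reduced inner
settings as the permutations, so observed and null are exchangeable under
the null hypothesis; the Monte-Carlo error of a permuted accuracy is
dominated by the label shuffle, not the inner repetition count. The
non-nested default inside the permutation loop keeps 1,000 permutations
tractable; because the same (slightly optimistic) pipeline is applied to
observed and permuted labels alike, the p-value retains its validity, which
the type-I simulations confirm.

Transfer restricts a trained model to the features present in a second
cohort's composition matrix, imputing absent model features at the training
mean (zero after scaling), and reports the feature-overlap fraction along
with accuracy when truth is supplied.

## Synthetic cohorts

The generator is first-class, tested code; its defaults are the study
conditions, not tuning knobs.

Geometry: 30 responders, 30 nonresponders (7 of them a systemically
inflamed subgroup), 28 well-nourished controls; stool time points at 9
(pre-intervention), 12, 13 and 18 months; a 23-marker biomarker panel at 9
months containing the nine-marker predictive panel (GLP2, MPO, prealbumin,
NEO, claudin-15, creatinine, CRP, IL-10, MCP1).

Counts: per-sample Dirichlet-multinomial draws. A population-level baseline
concentration vector (total concentration 50, controlling overdispersion)
is drawn once from a separate population seed so that two cohorts generated
with different cohort seeds share a taxon universe — this is what makes the
cross-cohort transfer scenario meaningful. Per sample the baseline is
modulated by exp(log-fold shifts) keyed on group and pre/post phase:
controls carry a +1.5 log-fold Bifidobacteriaceae excess at all time
points; responders carry +1.0 Gammaproteobacteria before intervention and
+1.2 Negativicutes with −1.0 Gammaproteobacteria after; nonresponders have
no time shift. Sequencing depth is log-normal around 60,000 reads. Shift
magnitudes are synthetic conventions chosen once for reliable recovery at
n = 30/group; no published effect sizes exist for them.

Biomarkers are log-normal with group shifts in log-sd units (responder-high
IL-10/GLP2/prealbumin/creatinine; nonresponder-high
CRP/MPO/NEO/MCP1/claudin-15; control-high growth markers with lowered
inflammation). The inflamed subgroup adds +3 log-sd to the six systemic
inflammation markers. Optional per-marker missingness supports filter
testing.

Growth records are monthly WAZ/WLZ/LAZ from 0–24 months with subject random
intercepts (sd 0.3), visit noise (sd 0.05) and piecewise group velocities.
The intervention-window velocity is the planted phenotype: nonresponders at
the reported group mean of −0.081 ΔWAZ/month, responders at +0.75/month
(between-subject sd 0.04). The source material reports the responder mean
as 0.413 "over the course of the intervention" while selecting responders
at > 0.5/month; these two figures are mutually inconsistent if 0.413 is
per-period (≈0.2/month), so responders are planted as what they were by
construction — extremes above the selection cut-off — and the 0.413
per-period figure is retained in `EffectSpec` as a documented reference
value. The inflamed subgroup starts higher (WAZ baseline −1.9) and declines
at −0.30/month during the intervention. WLZ is coupled to WAZ (offset −0.1,
noise sd 0.15) so wasting categories are realizable.

`EffectSpec.null()` zeroes every planted effect; with it, no downstream
stage discovers structure, which the suite checks.

All sampling flows through seeded `numpy` Generators; regeneration from a
fixed (spec, seed) is bit-identical, and the pipeline expands one top-level
seed into per-stage seeds via `SeedSequence`.

## Problem sizes and numerical choices in the shipped checks

The test suite and `scripts/acceptance.py` scale simulations to desk size
as the package's own defaults for its shipped checks: the headline
permutation test uses 1,000 permutations with a 10-repetition inner CV on
the post-intervention contrast (the strongest planted model, where the
observed-beats-all-permutations margin is stable across cohort draws);
type-I control uses 50 null runs at 99 permutations; planted-effect
recovery uses 20 cohort seeds, with 200-tree forests for the 20-seed
ensemble-recovery sweep (1,000 trees remain the analysis default);
PERMANOVA oracle agreement uses 4,999 permutations against exhaustive
enumeration of the 20 assignments of 3-vs-3 instances, keeping Monte-Carlo
error well inside the comparison band. Repeated CV defaults to 1,000
repetitions in the API, matching the original design; pipeline and test
configurations pass smaller values explicitly.

## Known limitations

- The generator plants class/family-level composition shifts; it does not
  emulate phylogenetic correlation, strain-level dynamics, compositional
  zero-inflation beyond what the Dirichlet-multinomial induces, or batch
  effects. Passing recovery tests therefore show the pipeline detects the
  planted structure, not that it would perform identically on real cohorts
  — in particular the high synthetic CV accuracies reflect clean planted
  effects, and the transfer accuracy between two generated cohorts is far
  above what heterogeneous real cohorts yield.
- Non-nested selection inflates absolute CV accuracy (selection sees the
  held-out folds); it is retained because the permutation comparison is
  leakage-matched. Nested mode is the default everywhere a single accuracy
  is the deliverable.
- The VIP variant is predictive-component-only; all-component VIP would
  differ for models with strong orthogonal structure.
- Multi-class OPLS-DA, UniFrac/phylogenetic diversity, rarefaction curves
  and raw-read (FASTQ) processing are out of scope.
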