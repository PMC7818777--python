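# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic cohort does and does not emulate,
and the numerical decisions a maintainer would need to know.

## Study design and data model

The unit of analysis is the matched case-control set: one case (a subject
who develops islet autoimmunity) with one matched control for the gene
expression block and three for the metabolomics and dietary-biomarker
blocks. Time is measured in months before seroconversion (MBSC) and binned
at 3-month intervals into five timepoints; bin b covers
[1.0, 1.5), [1.5, 4.5), [4.5, 7.5), [7.5, 10.5), [10.5, 13.5] MBSC for
timepoints 0, 3, 6, 9, 12. Bins are closed-left/open-right with the last
bin closed on both ends, so every printed boundary value has a unique bin;
measurements below 1.0 or above 13.5 MBSC are dropped with a logged count.
Multiple measurements of the same subject × feature × bin are averaged.
Timepoint order is descending MBSC (12 → 0) everywhere.

Each block becomes a 3-way array X (subjects × features × timepoints) with
an observation mask. Subjects observed (any feature) in at least 3 of the
5 timepoints form the analysis set; the rest form a per-timepoint
validation pool. Filtering is set-joint: if any member of a matched set
fails, the whole set moves to validation, because the model requires
complete case-control pairs.

**Within-normalization.** Per set, feature, and timepoint the set mean is
subtracted from every member. With m controls the mean control value is
computed first, then averaged with the case, so the case always carries
half the weight: for 1:1 sets normalized case + control = 0; for 1:m sets
normalized case + mean(normalized controls) = 0. If a member is missing
the mean uses the available members; a cell whose set has only one side
observed is set missing (to be imputed) rather than zeroed, since a
"difference from the set" is undefined there.

**Order of imputation and normalization.** The default is
impute-then-normalize (the workflow lists imputation before
normalization); the reverse order is a pipeline switch
(`normalize_before_impute`). After imputation the imputed cells are
treated as data for normalization, and the mask continues to mark them as
imputed in every exported bundle.

## Tucker3 imputation

Tucker3 factors X (I × J × K) into a core G (P × Q × R) and three
column-orthonormal loadings, fitted by higher-order orthogonal iteration
(ALS) from an HOSVD start — a deterministic initialization, so no seed
enters the decomposition. The explained-SS fraction is non-decreasing
across iterations (asserted at run time) and iteration stops when its
relative change falls below 1e-8.

Missing cells are imputed by fill–fit–replace: initialize with the mean of
the observed cells, fit Tucker3, replace missing cells with the
reconstruction, repeat. Convergence is declared when the relative change
in the sum of squared differences of the imputed cells between successive
iterations drops below 1e-7 (default); an alternative criterion — change in
reconstruction error on observed cells — is selectable. The imputed-cell
criterion was chosen because it directly bounds the movement of the
quantities being imputed. Non-convergence at `max_iter` returns the best
iterate with a warning rather than failing; on noise-dominated blocks the
fixed point can be approached slowly without affecting downstream results
materially. Observed cells are never altered. Imputation is strictly
per-block; tensors are never concatenated before imputation.

**Rank selection (DIFFIT).** All rank triples with P+Q+R ≤ s_max (default
9) are fitted; per total s the best fit is kept and dif(s) = fit(s) −
fit(s−1) computed (dif at the minimal total is the fit of (1,1,1) itself).
The selected s maximizes dif(s) relative to the largest gain at any higher
total. This deviates from the textbook next-step ratio dif(s)/dif(s+1) for
a numerical reason: ALS occasionally produces a near-zero single-step gain
mid-sequence (a local-optimum plateau), which makes the next-step ratio
explode at the wrong s; the max-over-later-gains denominator is immune to
such one-step flats while preserving the elbow logic (after the true
complexity, *every* later gain is small). Two guards keep the rule
parsimonious: totals with gain below 1e-4 of the total SS are not
candidates, and if no candidate reaches an elbow ratio of 3 the minimal
triple (1,1,1) is returned — structureless noise shows smoothly decaying
gains with ratios near 1.5 and lands on (1,1,1), while noiseless trilinear
data yields ratios above 1e6 at the true total. Ties break toward the
smaller total.

## NPLS-DA

Trilinear PLS2 in the response-deflation-only form. With X centered across
subjects and Y the centered class-indicator dummy matrix, component h is
obtained from Z = X₍₁₎' Y_res (the covariance unfolding): its leading left
singular vector, reshaped J × K and decomposed rank-1, gives unit-norm
feature weights w_j and timepoint weights w_k; the subject score is
t_h = X₍₁₎ (w_j ⊗ w_k). The response is deflated by regression on the
accumulated scores; X is never deflated, so scores remain exact tensor
contractions with the weights at every component (a tested invariant).
Sign convention: the largest-magnitude entry of w_k, then of w_j, is made
positive; with a single timepoint the model therefore coincides exactly —
weights and scores — with two-way PLS under the same convention, which the
test suite checks against an independent matrix-space implementation and
against scikit-learn's first component.

The discriminant layer is LDA on the subject scores (default) or the inner
regression with an argmax rule; posterior ties resolve to the first class
in sorted order. R²Y and Q² = 1 − PRESS/TSS are computed on the continuous
dummy response; the classification rate is reported separately.

**Pair-grouped cross-validation.** Within-set normalization makes a case's
profile the exact mirror of its control's, so folds that separate a
subject from its partners leak the label: measured on zero-effect
synthetic cohorts, subject-level 5-fold CV yields Q² around 0.5 while
pair-grouped CV yields Q² ≤ 0. When pairing is known, a held-out subject's
partners are excluded from its training fold. LOO still performs exactly
one fit per subject; k-fold assigns whole sets to folds (each set contains
both classes, so folds remain stratified). k-fold Q² is averaged over
`n_repeats` random fold assignments; LOO has no repeat randomness.

**Multiblock integration.** The integrated model concatenates the selected
features of each block on the shared subjects, after scaling each block to
unit total SS so no block dominates the covariance. The number of
components defaults to 2; the parsimony rule (smallest H within 0.01 of
the best CV Q² over H = 1..5) is available where model order is free.

## VIP selection

Wold's VIP with unit-norm component weights:
VIP_j = sqrt(p · Σ_h SSY_h w_jh² / Σ_h SSY_h), where SSY_h is the response
SS explained by component h; Σ_j VIP_j² = p holds for the two-way
computation (tested to 1e-8). Three arrangements:

- `vip2d`: two-way VIP on the subjects × (features·timepoints)
  matricization — one value per variable per timepoint, collapsed per
  variable by max (default; mean optional). The "wide matrix" reading is
  the full unfolding; a pairwise adjacent-timepoint variant was considered
  and rejected as it discards cross-window covariance.
- `vip3d_model1`: the time mode is constrained — only feature weights
  enter, normalized over J, one value per variable.
- `vip3d_model2`: per variable × timepoint × component values from the
  Kronecker element w_jh·w_kh, summed over timepoints, averaged over
  components.

Thresholding keeps variables strictly above a percentile of the block's
own VIP distribution (linear interpolation; ties at the threshold are
excluded). Defaults are the 99th percentile for gene expression and 95th
for metabolomics-like blocks; note the 99th presumes 10⁴-scale blocks — on
synthetic blocks of ~10² features the equivalent top-few-percent intent
corresponds to the 95th, which the demonstration script uses for all
blocks. The candidate search evaluates the three per-strategy sets plus
all pairwise and three-way unions and intersections (deduplicated,
empties dropped), refits and cross-validates each, and keeps the highest
Q² (ties: higher R², then smaller set).

## Validation

Permutation significance compares the selected set's R²/Q² against
`n_permutations` refits with (a) uniformly drawn same-size feature sets or
(b) labels flipped within matched sets — the exchangeable unit under
pairing; unpaired shuffling is available. p = (1 + #{null ≥ observed}) /
(n + 1), one-sided with the +1 correction. Type-I error is verified by
simulation: on zero-effect cohorts the empirical rate at α = 0.05 stays
within 0.03 of nominal over 200 runs.

Subjects excluded by the completeness filter are validated per timepoint:
an LDA (pooled covariance; lsqr solver with analytic shrinkage when
features ≥ samples) is trained on the analysis subjects' selected-feature
slice at one timepoint and applied to validation subjects observed there.
Training slices are within-normalized while validation subjects, lacking
complete sets, are raw, so both slices are mean-centered per feature to
share a scale. Cross-timepoint prediction (train at 12 MBSC, predict any
timepoint) is supported. Timepoints with fewer than two evaluable samples
or one observed class report NaN rather than failing.

## Partial-correlation networks

Disease-progression profiles are differences of normalized case values
between consecutive timepoints, later minus earlier (the progression
direction; the sign choice only mirrors node annotations), giving four
windows: 12to9, 9to6, 6to3, 3to0. Per window, an elastic-net bootstrap
picks high-variability features: for each mixing value α ∈ {0, 0.1, …, 1}
(ridge to lasso), `n_tune` logistic fits on bootstrap resamples are scored
by out-of-bootstrap deviance; `n_final` fits at the winning α collect
every feature with a nonzero coefficient at least once. The response is
the case/control outcome over all normalized subjects' window profiles
(the alternative unsupervised PC1 response is available); the paper-style
analysis never names its response, so this choice is flagged as a design
decision, not an inference about intent.

Partial correlations are full-order: pcor(i,j) = −P_ij/√(P_ii P_jj) from
the precision matrix P. With n ≤ p + 10 the covariance is first shrunk
toward its scaled identity with the Ledoit-Wolf analytic intensity
(otherwise the empirical covariance is inverted); an exactly collinear
pair raises an error naming the columns. The matrix is computed over the
full selected signature per window; the exported network displays only
that window's elastic-net selection, with edges at |pcor| > 0.7, edge sign
annotations, and node annotations (molecule kind gene/metabolite/vitamin;
up/down regulation from the mean normalized case value at the window's
first timepoint). Raising the threshold can only remove edges (tested).
Window distributions are compared on the full-signature off-diagonal
values by excess kurtosis (negative = platykurtic: relatively more
extreme correlations; positive = leptokurtic) and two-sample KS tests
between consecutive windows.

## Enrichment

Gene sets are scored per timepoint by permutation on the VIP ranking:
the observed statistic is the sum (and mean) of member values, the null
redistributes gene labels, p = (1 + #{null ≥ obs})/(n_perm + 1). For a
fixed set size the mean is a monotone transform of the sum, so the two
modalities' permutation p-values coincide; both are computed and the
minimum retained for interface fidelity. Gene-label (not sample)
permutation is used because only rankings enter this operation.
Per-timepoint p-values are combined over every non-empty timepoint subset
(configurable cap) with Fisher's method, −2Σln p ~ χ²(2k); BH runs across
sets within each combination and a set is selected when any adjusted
p ≤ 0.05. The signed display score is (1 − p) × sign(mean value of the
significant member genes), 0 when none are significant.

Metabolite classes: per timepoint, a paired t-test (case vs mean-control
profile per set; Welch without pairing) flags metabolites at p < 0.05;
each class with ≥ 2 members gets a one-sided Fisher exact test on the
in-class × significant 2×2 table; BH across classes, kept at FDR ≤ 0.2
with a direction annotation from the significant members' mean difference.
Semantic deduplication of redundant pathways is curation, not computation,
and is out of scope.

## Synthetic cohort

The generator emulates: the matched design (1 or 3 controls per case per
block), five 3-month MBSC bins with sampling-time jitter inside bin
boundaries, block sizes of order 10¹–10², a planted additive case-only
effect of size `effect_size`·`noise_sd` modulated by the per-timepoint
profile (1.0, 1.0, 0.6, 0.4, 0.4) — strongest a year before seroconversion,
mirroring the early-signal regime the pipeline is meant to detect — a
subject-level random intercept (SD = 0.5·noise_sd) that makes within-set
normalization non-trivial, and visit-level MCAR missingness (whole
subject × timepoint × block vectors, as happens when visits are missed)
repaired so analysis subjects keep ≥ 3 observed timepoints; `missing_rate`
must stay below 0.4 for that constraint to be satisfiable. Optional extra
pairs with 1–2 observed visits populate the validation pool.

It does **not** emulate: raw array/chromatogram signals, batch effects,
feature-feature correlation or pathway co-regulation, non-Gaussian
abundance distributions, or informative missingness. Passing tests
therefore demonstrate correctness of the algorithms and calibration of the
statistics under a clean additive-Gaussian regime, not robustness to the
artefacts of real multi-omics data.

Default problem sizes (40 analysis pairs, blocks of 150/80/10 features in
the demonstration script) were chosen as the smallest sizes at which every
stage of the method is exercised meaningfully — pair-grouped CV has enough
sets per fold, percentile selection keeps several features, and the
p > n shrinkage route of the network stage is reached.

## Known limitations

- Binary outcomes only; the discriminant layer does not handle more than
  two classes.
- The integrated model assumes the case subjects are shared across blocks
  (true for the matched design it models).
- Permutation tests refit the full model per draw; counts beyond ~10³ are
  computationally heavy at large block sizes.
- The DIFFIT search space is capped by total rank, not per-mode, so very
  anisotropic true ranks (e.g. (1, 8, 1)) require raising `max_total_rank`.
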