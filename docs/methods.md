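# Methods

## Model and statistic

For a metabolite pair (i, j) the within-group Pearson correlations r₁
(pre) and r₂ (post) are compared through the weighted Fisher-z difference

    r_diff(i,j) = √((n₁−3)/2) · atanh(r₁) − √((n₂−3)/2) · atanh(r₂).

Under bivariate normal sampling atanh(r) is approximately normal with
variance 1/(n−3), so each weighted term has variance ½ and r_diff is
approximately standard normal under the null of equal population
correlations, for any pair of group sizes; when n₁ = n₂ = n it reduces to
the familiar √((n−3)/2)·(z₁ − z₂). The subtraction order is
pre-minus-post by default; because practitioners sometimes report the
opposite convention, `direction="post_minus_pre"` flips the reported sign
(permutation p-values are unaffected, the statistic being two-sided).

Significance is assessed by a group-label permutation test: B relabelings
(default 1000) that preserve the two group sizes, the *same* permutation
set reused for every pair — a single joint test preserves the cross-pair
dependence structure — and the two-sided add-one estimator

    p_perm = (1 + #{b : |r_diff,b| ≥ |r_diff,obs|}) / (B + 1),

which is never zero and is floored at 1/(B+1). Seeded runs are
bit-reproducible. The analytic N(0,1) tail is used only as a test oracle,
never as the reported p-value: on skewed concentration scales the
permutation null is the defensible reference.

Within-group correlation screens use the full-pair-count Bonferroni rule
(raw p < α / [m(m−1)/2], strict) and the overlap fraction
|pre ∩ post| / |pre| summarizes how much correlation structure is shared
"housekeeping" biochemistry.

## Preprocessing chain

Fixed order: measurability filter → below-LOD fill → covariate
residualization → mean imputation → z-normalization.

* *Measurability*: a metabolite is kept when quantified in ≥ 80% of
  samples (inclusive boundary). Below-LOD and missing entries both count
  as non-measurable — below-LOD is a detection failure.
* *Below-LOD fill*: half the minimum quantified concentration of that
  metabolite, both groups pooled. A metabolite entirely below LOD is an
  error, not a guess.
* *Covariate adjustment*: OLS residuals of each metabolite on
  [intercept, age, BMI, activity, age of menarche], fit on both groups
  pooled (adjustment precedes, and is blind to, any group comparison);
  entries still missing are excluded from the fit and stay missing.
  Permutations downstream do NOT re-fit the adjustment — it is group-blind,
  so relabeling cannot change it.
* *Mean imputation*: metabolites missing in < 5% of samples are filled
  with the all-sample mean of the (residualized) column; at/above 5% the
  metabolite is dropped with a warning. Imputation is applied after
  residualization, matching the order in which the steps are defined.
* *Normalization*: z-score over all samples (ddof = 1); exactness claims
  (zero means, unit SDs, residual–covariate orthogonality) hold to 1e-8.

The cohort summary (per-covariate group mean ± SD with a Welch
unequal-variance t-test) is descriptive bookkeeping only.

## Network topology

Selected edges (p_perm ≤ 0.01, inclusive) form an undirected simple graph;
|r_diff| and the sign are edge attributes but play no role in path
computations — the named centralities have no standard weighted-path
definition here, so the unweighted topology is used. Degree is the raw
neighbour count; betweenness excludes endpoints and is normalized by
(N−1)(N−2)/2; closeness is the classical within-component definition
(n_comp − 1)/Σd. Hubs are ranked by degree with betweenness then name as
tie-breaks; bottleneck flags mark the top decile (configurable) of
betweenness or closeness. Exports: GraphML and edge-list CSV, round-trip
safe including the "negative"/"positive" sign strings.

## OPLS-DA stage

Single-response NIPALS: w ∝ Xᵀu (u the centred 0/1 class indicator) is
computed once and unit-normalized; each orthogonal component takes the
loading p of the current predictive score, removes its projection on w,
and deflates X by the resulting orthogonal score/loading; the predictive
component is then fit on the filtered matrix. The construction makes the
predictive and orthogonal score vectors exactly orthogonal. Defaults:
one orthogonal component (n_orth selection is out of scope); with
n_orth = 0 the model equals a one-component PLS-DA fit (verified against
an independent PLS implementation in the tests).

VIP is computed on the predictive component; for one component it is
√m·|w_j|, so Σ VIP² = m identically — asserted on every fit. Q² uses
7-fold class-stratified cross-validation with seeded fold assignment
(a common chemometrics default; per fold, columns are re-centred/re-scaled
with training statistics and PRESS/TSS accumulate over held-out samples).
The screen passes metabolites with VIP > 1 (strict) *and* Welch-t
p < α/m (strict); the threshold is reported both exactly and truncated to
two significant digits, the form in which such thresholds are printed
(0.05/168 → 2.9×10⁻⁴). The univariate test behind the screen is Welch's t
on the normalized values — a deliberate choice where several tests would
be defensible. Association of screened candidates is OLS of the adjusted
metabolite on the binary group indicator; with a binary predictor the
slope equals the between-group mean difference exactly.

## Synthetic-data generator

The generator emulates the study design the package targets: 55 pre- vs
64 post-group samples (the emulated cohort reports 120 participants but
55 + 64 = 119; the group sizes are taken as stated), ~168 quantified
metabolites, age distributions N(39.4, 9.1²) and N(57.2, 8.5²) by group,
group-invariant BMI (29.2 ± 5.6), activity (7.8 ± 1.6) and age of
menarche (12.8 ± 1.8).

Latent values are multivariate normal per group with a correlation matrix
assembled from shared housekeeping blocks (default (10, 0.6), (8, 0.5),
(6, 0.4) — chosen so that most Bonferroni-significant correlations are
shared between groups, as in real panels) plus planted differential
pairs. Non-positive-definite assemblies are repaired by eigenvalue
clipping at 1e-6 followed by re-normalization to unit diagonal
(deterministic, approximately target-preserving; whether repair occurred
is recorded). Latent values map to concentrations via exp(µ_j + σ_j·z)
with µ_j ~ U(ln 0.5, ln 50) and σ_j ~ U(0.2, 0.4) — a right-skewed
µM-scale panel with moderate per-metabolite spread. Correlations are
therefore planted on the latent (log) scale, where they hold exactly for
log concentrations; Pearson correlations of the raw exponentiated values
are mildly attenuated (for σ ≈ 0.3, a planted 0.70 appears as ≈ 0.69),
which the recovery tests absorb.

Covariate effects are linear slopes on the log scale applied to the
centred covariate; because age differs by group, an age effect creates
confounded between-group structure by design, letting tests verify that
residualization removes it. Censoring flags the round(q·n) lowest values
of each metabolite below LOD (default q = 0.02); missingness flags
round(0.02·n) entries per metabolite — allocated per metabolite so the
5% drop rule is never tripped by the generator itself. Ground truth
stores the *target* correlations, not realized ones: recovery is judged
against the generative truth.

What the generator does not emulate: mass-spectrometry peak data, batch
or plate effects, heavy-tailed analytical noise, metabolite-class
structure, and group mean shifts in metabolite levels (it plants
correlation differences only). Consequently the end-to-end OPLS-DA Q² on
generator output sits at or below zero — the correct null answer — and the
discriminant stage's power properties are exercised on constructed
mean-shifted matrices in the tests and examples. Passing tests show the
machinery is correct and calibrated under these conditions, not that any
particular real-data finding is reproduced.

## Problem sizes and numerical choices

The statistical suites run at the emulated design size (n = 55/64,
B = 1000): null calibration uses a 100-metabolite independent panel
(4950 pairs; uniformity and type-I checks use 50 metabolite-disjoint,
hence independent, pairs); recovery uses 50 replicates of a 20-metabolite
panel with three planted pairs of |Δr| ≥ 0.5 — panel size, not sample
size or permutation depth, is scaled down, since pair count does not
affect per-pair power. Exactness tolerances: 1e-8 for preprocessing
claims, 1e-6 for score orthogonality and the VIP identity, exact equality
for permutation counts against the naive oracle. Ties in |r_diff| between
a permuted and the observed statistic count toward the p-value (the ≥ in
the estimator). Degenerate inputs fail loudly: perfect correlations
(|r| = 1) raise rather than clamp, as do zero-variance metabolites,
all-censored metabolites and rank-deficient covariate designs.
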