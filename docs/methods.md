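# Methods

## The model

The package infers which transcription factors (TFs) best explain the
expression of a modelled gene (the motivating case is MITF, the melanocyte
master regulator) across a panel of samples, and follows the selected
regulators into clinical endpoints.

**Edge strengths.** Binding evidence for a TF *t* and a target gene *i* is
integrated into a nonnegative edge strength es_{t,i}. A pair is *reliable*
if it carries a curated "direct" annotation (activation or inhibition), or
if at least two of {curated "indirect" annotation, ChIP-compendium hit,
consortium-ChIP hit, TBA z-score ≥ 1} support it. For reliable pairs, es is
the count of set flags among the five counted categories (ChIP compendium +
the four curated categories) plus the TBA z-score when it is ≥ 1; for
unreliable pairs es = 0 and the pair is ignored. Two conventions are fixed
here because the enumeration leaves them open: the consortium-ChIP flag
contributes to reliability but not to the count (a switch can include it),
and a TBA z-score of exactly 1.0 counts for both rules. A missing TBA score
contributes nothing (it is not treated as zero). The consortium ChIP matrix
is first collapsed to one row per target (intersection of duplicate rows)
and one column per TF (union of duplicate columns).

**Activity.** The activity of TF *t* in sample *j* is the edge-strength
weighted mean of its targets' z-scored expression,
act_{t,j} = Σ_i es_{t,i} g_{i,j} / Σ_i es_{t,i}. It is a weighted mean, so
it is bounded by the targets' expression range, invariant to rescaling a
TF's weight row, and reduces to the arithmetic mean for equal weights.
Targets absent from the expression matrix are dropped from numerator and
denominator alike. By default the modelled gene itself is excluded from its
regulators' target sets, so the response cannot leak into the predictors; a
switch restores inclusion.

**Best-subset LAD regression.** The response is predicted as
g̃_j = β0 + Σ_t β_t·act_{t,j}, minimising Σ_j |g_j − g̃_j| subject to at
most k nonzero coefficients. Cardinality is encoded with binary indicators
z_t and big-M bounds −M z_t ≤ β_t ≤ M z_t, Σ z_t ≤ k ("at most", not
"exactly": with redundant regressors this matches the intent and never
worsens the objective). The MILP is solved with HiGHS via
`scipy.optimize.milp` at a relative MIP gap of 1e−6; HiGHS is deterministic
for a fixed problem, so refits reproduce exactly. M defaults to 1e3 — on
z-scored data plausible |β| is O(1), and the fit warns if any |β| exceeds
0.9·M. After the integer solve, the selected support is polished by an
exact LP refit: the solver's integrality tolerance can leave |β| up to
M·tol on a nominally unselected regressor, and the polish removes that
dust from the reported coefficients and objective. k = 0 uses the closed
form (the L1-optimal intercept is the median); k ≥ T and fixed supports
use a plain LP.

**Scanning and validation.** A bottom-up scan refits at k = 1, 2, …, the
solver choosing the support freely each time (selected sets need not nest —
a near-collinear proxy regressor can win at k = 1 and be displaced at
k = 2). Each k is scored by leave-one-out cross-validation: refit on l − 1
samples (support selection included), predict the held-out sample, and
report the Pearson correlation between the pooled held-out predictions and
the measured response. Pooling is the only option under LOO — folds of size
one have no within-fold correlation. Transfer prediction applies frozen
coefficients to a second cohort's activities and reports the Pearson
correlation there. Undefined correlations (constant vectors) raise, they
are never silently reported as 0.

## Clinical follow-up

**Thickness model.** Breslow thickness is fitted on the raw expression of a
small gene set (not activities) by the same LAD machinery with k = number
of regressors, i.e. an unconstrained L1 fit, scored by LOO-CV. Staging
subgroups use thin ≤ 1 mm, intermediate (1, 4] mm, thick > 4 mm; the
boundary convention is configurable because staging tables are printed
inconsistently in the literature (1 mm and 4 mm are assigned to the lower
group here).

**Survival cutpoint.** For a candidate threshold c the cohort splits into
expression < c vs ≥ c and the standardized two-sample log-rank statistic
Z(c) = U/√V is computed (vectorised over all candidates; ties grouped).
Candidates are the observed expression values leaving at least 10 % of
samples on each side, so the selected cutoff transforms exactly under
monotone maps of the expression scale. A 10-fold cross-validation wrapper
(folds seeded, stratified by event status so no training set is event-free)
selects the per-fold maximising threshold on each training portion; the
final cutoff is the lower median of the fold cutoffs. The lower median — an
element of the list rather than a midpoint — keeps the combined cutoff an
observed candidate value, preserving exact monotone equivariance.

The reported p-value at the final cutoff corrects for maximal selection
with the Lausen–Schumacher (1992) tail approximation for the supremum of
the standardized log-rank process over the allowed split range (the same
approximation behind R's maxstat). This is a deliberate design choice: the
training folds of a 10-fold CV share 90 % of their samples, so the
median-of-folds cutoff is in practice the full-sample maximally selected
cutoff, and simulation shows the naive log-rank p at that cutoff rejects a
true null at ≈ 35 % instead of 5 %. With the correction the null rejection
rate is ≈ 4 % while a planted hazard ratio of 3 (n = 200) still yields
p < 0.001 essentially always. The uncorrected p is kept alongside
(`logrank_p_uncorrected`) for comparability with reports that quote a plain
log-rank test.

**ΔΔCt.** Fold changes use the Livak method: per condition the median Ct of
technical replicates per gene, ΔCt = Ct_GOI − Ct_HK, ΔΔCt = ΔCt_treated −
ΔCt_control, FC = 2^(−ΔΔCt). The second difference is taken on ΔCt values
(not raw Cts), which makes the fold change invariant to a constant shift of
all Cts and gives FC(t,c)·FC(c,t) = 1. No amplification-efficiency
correction is applied. Summaries across biological replicates (mean of fold
changes vs fold change of mean ΔΔCt) differ; per-replicate fold changes are
returned and the summary is left to the caller.

## Synthetic data

The generator plants a known regulatory structure so every stage is
testable without external cohorts. Defaults are the study conditions used
throughout the tests: 19 candidate TFs, 40 samples, one planted activator
(β = +1.5) and one planted inhibitor (β = −1.0), response noise σ = 0.2,
10 private targets per TF with target-level noise σ = 0.2, intercept 0.5.
Each TF has a latent standard-normal driver; the inhibitor's driver is a
two-component Gaussian mixture (weight 0.5, means ±1.5, sd 0.5) emulating a
regulator whose expression across tumours is bimodal. Target rows are
driver + noise, z-normalised; the response is the linear combination of the
*computed* activities of the planted TFs plus noise, so at zero noise it
lies exactly in the model class and exact recovery is a meaningful test.
Edge strengths are drawn from the representable set (integer hit counts
1–3, optionally plus a TBA score in [1, 2]) so evidence records can be
reconstructed that round-trip exactly through the integration rules.

Clinical tables are linked back to the planted data: thickness is a noisy
linear readout of designated gene rows (clipped at 0.1 mm), and survival is
exponential with baseline hazard 1/1000 per day, multiplied by a hazard
ratio (default 3) when a designated gene's expression is below the planted
cutoff, under independent exponential censoring tuned to ≈ 30 %.

What the generator does *not* emulate: platform/batch effects, correlated
target sets shared between TFs, non-Gaussian expression noise, dependent
censoring, covariate-driven hazards. Passing tests therefore demonstrate
correctness of the algorithms and recoverability under clean planted
conditions, not performance on real cohort data.

## Normalisation and missing data

Expression z-scores use the population standard deviation (divide by n),
the common microarray convention; constant rows are dropped with a warning.
The raw-intensity chain (for MAS5-style data) floors values at 0.01,
divides each sample by its 50th percentile, each gene by its median across
samples, then z-scores — making it invariant to per-sample rescaling.
Missing values: samples with more than 10 % missing genes (configurable)
are excluded, the rest are mean-imputed per gene; a gene with no observed
value raises.

## Problem sizes and numerics

The test suite and the acceptance script size their simulations to the
study conditions above: 100 seeds for planted-pair recovery, 5 seeds
(200 held-out predictions) for pooled LOO-CV, 50 random instances at
T = 8 / n = 12 / k ≤ 3 for the enumeration cross-check, 50 seeds for
cutpoint recovery and 200 for null calibration at n = 200. MILP/LP
tolerances: HiGHS defaults with mip_rel_gap 1e−6; oracle comparisons use
1e−6 absolute. Tie-breaking between equally optimal supports follows the
solver's deterministic variable order.

## Known limitations

* The big-M formulation weakens the LP relaxation for very large M; with
  heavily unscaled responses, rescale first or set `big_m` explicitly.
* LOO-CV refits one MILP per sample; for T in the hundreds a warm-started
  or decomposition-based approach would be needed.
* The Lausen–Schumacher approximation is asymptotic; for very small cohorts
  (< ~50 samples or < ~10 events) the corrected p is only indicative, and
  the CV wrapper refuses to run below 30 samples / 10 events.
* Activities are unsigned; activation vs inhibition is carried entirely by
  the sign of the regression coefficients.
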