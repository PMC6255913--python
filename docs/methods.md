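# Methods

`bloodmark` implements a blood-transcriptomic discovery workflow for
Alzheimer's disease (AD): covariate-adjusted differential expression
across merged cohorts, cross-tissue overlap and concordance statistics,
gene-set overrepresentation, and a repeated-LASSO / voting-ensemble
biomarker-panel procedure. This note records the models, the defaults and
why, the numerical choices, and what the synthetic-data tests do and do
not establish.

## Differential expression: moderated t

Per feature g, log2 expression is regressed on an intercept, a two-group
contrast indicator (AD vs CTL, MCI vs CTL, or AD vs MCI; coefficient =
first-named minus second), and adjustment covariates (age in years,
female indicator, optional extras) by ordinary least squares. Gene-wise
residual variances σ̂²_g (d degrees of freedom each) are modelled
hierarchically as scaled inverse-chi-square draws around a prior
(d0, s0²). The hyperparameters are estimated by moments on
z = log σ̂²_g: with e = z − ψ(d/2) + log(d/2),

    trigamma(d0/2) = Var(e) − trigamma(d/2)      (solved by Newton, tol 1e-8)
    s0² = exp( mean(e) + ψ(d0/2) − log(d0/2) )

If Var(e) is at or below the pure-sampling value trigamma(d/2), the prior
is a point mass: d0 = ∞ and s0² is the arithmetic mean of the σ̂²_g.
The posterior variance s̃²_g = (d0·s0² + d·σ̂²_g)/(d0 + d) yields the
moderated t = β̂_g / (s̃_g √v) on d0 + d df (two-sided p; normal when d0 is
infinite). Setting d0 = 0 recovers ordinary per-gene t-tests, which the
tests verify to 1e-10; agreement with Bioconductor limma's `lmFit` +
`eBayes` on shared data is verified to ~1e-8 in the suite.

Fold change is reported as FC = 2^β̂ (FC < 1 = down-regulated).
Significance is BH-adjusted p < 0.01 by default, with a `nominal` mode
(p < 0.01) for low-powered validation cohorts where nothing survives
multiple testing.

## Merging and residualisation

Two cohorts are merged on the intersection of their features. The default
batch adjustment subtracts each feature's per-batch mean — the minimal
adjustment that removes additive batch offsets and leaves within-batch
contrasts untouched. An `eb_location_scale` alternative additionally
shrinks per-batch feature locations and scales toward across-feature
priors (normal / inverse-gamma fit by moments, the usual parametric
empirical-Bayes fixed point) before removing them — appropriate when
batches differ in variance, at the cost of mild shrinkage bias. The
method used is recorded in the run metadata.

For machine learning, each cohort is residualised *independently*: per
feature, expression is regressed on intercept + age + gender by Huber
M-estimation (tuning constant 1.345 — the standard 95%-efficiency choice;
scale re-estimated each IRLS iteration as 1.4826 × median |residual|;
at most 50 iterations; convergence when the largest coefficient change is
below 1e-8). Non-converging features fall back to least squares and are
flagged; constant features get zero residuals, are flagged, and are
excluded from the ML feature pool (never divided by a zero scale).
Residuals are centred and scaled to mean 0, sd 1 (ddof = 1). When no
residual exceeds the Huber threshold the weights are all one and the fit
is exactly OLS; with unbounded Gaussian noise the M-estimator deviates
from OLS by design (the ψ function clips the largest ~18% of residuals),
so exact-agreement checks are meaningful only for bounded noise.

Probeset-level results collapse to genes by taking the probeset with the
smallest unadjusted p as the gene's representative (a gene is significant
iff any of its probesets is). Minimum-p rather than averaging preserves
"top DEG" rankings across cohorts.

## Overlap, concordance and overrepresentation

Cross-list enrichment uses the 2×2 Fisher exact test over an explicit
universe (the intersection of the gene sets tested in both studies —
printed odds ratios in the literature depend on this convention, so it is
fixed and logged). The odds ratio is the conditional MLE of the
noncentral hypergeometric parameter (the R `fisher.test` convention, not
the sample cross-product); the two-sided p follows the minimum-likelihood
rule. The 95% CI is the exact conditional interval when the smallest
margin is ≤ 200 and no cell is zero; larger tables use the Woolf log-OR
normal interval, and a zero cell forces Woolf with a 0.5 continuity
correction and a degeneracy flag. A zero row/column margin makes the OR
undefined (flagged result, p = 1).

Direction concordance between two DEG tables is the fraction of
shared-significant features with the same regulation direction, tested
against 0.5 by the exact two-sided binomial (sign) test. Region overlap
tables report, per brain region, the fraction of its DEGs also
significant in blood, rounded half-up to 2 decimals to match printed
precision. Trait association thresholds per-gene correlations at
|r| > 0.5 and reuses the Fisher machinery.

Overrepresentation (ORA) restricts each gene set to the universe, uses
the upper-tail hypergeometric p = P(X ≥ k), BH-corrects across the
collection, and flags significance at BH < 0.01. Sets with no in-universe
members are skipped with a warning.

## Panel discovery

Feature selection: L1-penalised logistic regression over a geometric grid
of 100 penalties spanning 4 decades below λ_max = max|Xᵀ(y − ȳ)|/n. Per
repeat, a fresh stratified 5-fold split scores the grid by mean
out-of-fold ROC AUC; the model is refit on all training data at the
winning penalty (ties resolve to the larger penalty, i.e. the sparser
model) and its nonzero support becomes one candidate. Candidates are
aggregated by exact feature-set identity with a selection frequency and
mean CV AUC. Panel choice: `best_auc` (default; ties by frequency then
smaller panel) or `most_frequent` (ties by AUC); in both rules candidates
with fewer than two features are skipped in favour of the next-ranked
candidate — a one-gene "panel" is not accepted.

Ensemble: an RBF-kernel SVM (C = 1, kernel width 1/(p·Var(X))), a
500-tree random forest (√p candidate features per split), and an L2
(ridge) logistic regression whose penalty is tuned by stratified 5-fold
CV AUC on training and whose decision cutoff is derived from the training
scores: candidate cutoffs are midpoints between adjacent sorted unique
scores; accuracy decides, Youden's J breaks ties, then the smaller
cutoff. These hyperparameters are pinned explicitly (library "defaults"
differ across ecosystems) and logged. The final label is the majority of
the three model labels (three voters — no ties); the vote AUC is the
arithmetic mean of the three model AUCs, reported at 3 decimals
(score-averaging is available but not the default). Class-weight
adjustment (inverse frequency) is available for imbalanced cohorts,
off by default.

Evaluation: ROC AUC as the rank statistic with ties counted half
(verified against exhaustive pair counting); AUPR by step-wise
precision-recall integration (the average-precision estimator); accuracy
with the exact Clopper–Pearson 95% CI; sensitivity/specificity from the
vote confusion counts. The cross-dataset protocol trains on one cohort
and tests on the other, then swaps; when the test cohort has MCI samples
the fraction voted into the AD class is reported (MCI transfer rate).

A calibration caveat the tests encode: for a single Gaussian feature with
standardized class separation Δ, the optimal AUC is Φ(Δ/√2). Only a
scorer monotone in the feature (the ridge logistic) attains it; the
forest's step-function scores and the RBF-SVM sit a few points below it
at n = 300 — behaviour shared by the R reference implementations — so the
closed form is asserted as a calibration target for ridge and as an upper
bound for all three.

## Synthetic cohorts

`generate_cohorts` emulates the structure of a two-cohort blood
microarray study:

    y_gi = baseline_g + effect_g(group_i) + slope_g·(age_i − mean age)
           + offset_g·female_i + batch_gd + N(0, σ_g)

* Group sizes default to 143/77/104 and 102/65/78 (AD/MCI/CTL) — the two
  cohorts the workflow targets. Features default to G = 4000 (a scale
  chosen so the full pipeline runs in seconds; the moment estimators are
  already stable well below this).
* A fraction π1 = 0.2 of features carry AD effects drawn uniformly from
  ±[0.1, 0.5] log2 units — matching the small fold changes typical of
  blood (FC ≈ 0.7–1.3). MCI effects are 1.2× the AD effects on the same
  features (prodromal changes at least as large as AD), with direction
  flipped for a configurable 1 − concordance fraction (default
  concordance 1: common DEGs share direction).
* Noise variances are scaled inverse-chi-square (d0 = 4, s0² = 0.05), so
  the moderation stage has a well-specified recovery target.
* Age (N(75, 7²) years, clipped to [40, 100]) and gender (Bernoulli 1/2)
  affect 30% of features with slopes ±[0.01, 0.05] per year and offsets
  ±[0.1, 0.3], giving the residualisation stage real work.
* Each cohort gets an additive per-feature batch offset, N(0, 0.5²).
* A small panel (default 4 features) receives an extra AD–CTL separation
  of Δ·σ_g (default Δ = 1), and mci_attenuation times that for MCI.

All randomness flows from one integer seed through fixed sub-streams;
identical configurations are bit-identical. Every planted quantity is
recorded in a JSON truth file that round-trips without re-running the
generator. The panel-recovery configuration (`recovery_config`) zeroes
the DEG effects so the planted panel is the only group signal — the
recovery question is "does the selection find the planted discriminative
features", not "does it prefer them to equally discriminative DEGs".

What the generator does *not* emulate: probe-level intensities and array
artifacts, correlated gene modules, platform-specific probe behaviour,
non-Gaussian expression tails, or confounding between diagnosis and the
covariates. Passing recovery tests therefore show the procedures are
correct and calibrated under their own assumptions, not that the panel
sizes or AUCs would transfer to real cohorts.

## Problem sizes and simulation scales

Simulation scales are package choices balancing statistical resolution
against turnaround: hyperparameter recovery uses G = 5000 over 20
replicates; FDR control uses 50 cohorts of G = 2000 with 30 samples per
group; panel recovery uses the recovery configuration (G = 1000, 125 AD +
125 CTL per cohort) over 10 seeds with 3 LASSO repeats — the candidate
frequencies stabilise within a handful of repeats at the planted effect
sizes, so the 100-repeat default is reserved for real, weaker-signal
data; the overlap-list round trip uses a 20 000-gene universe over 20
seeds. The oracle sweeps are exhaustive where enumeration is feasible
(every 2×2 table with N ≤ 40).

## Known limitations

* The merged-cohort analysis fits no explicit batch term by default
  (batch structure is removed before fitting); adding batch as a model
  covariate is available by flag.
* Residualisation is fit per dataset (merge first and residualise the
  merged matrix for a joint fit); with strong cohort-covariate
  interactions the two differ.
* The ORA universe and enrichment background conventions materially
  change printed odds ratios; results are comparable only within a fixed
  convention.
* No APOE4 stratification, probability calibration, or network-based
  selection; pairwise contrasts only.
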