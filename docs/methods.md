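# Methods

## The problem and the model

Prognostic gene signatures for acute myeloid leukemia (AML) are usually
linear scores over absolute expression values. Such scores travel poorly
between cohorts: microarray and RNA-seq data have different distributions,
and per-cohort processing shifts and warps expression, so a risk cutoff
fitted in one cohort rarely transfers to another. The gene-pair
(relative expression ordering) approach replaces each expression value
with a binary within-sample comparison,

    I(A|B) = 1  if expr(A) > expr(B),   0 otherwise (ties -> 0),

which is invariant to *any* strictly increasing per-sample transform of
the data — affine rescaling, log/exp warps, rank normalisation — and
therefore to the batch effects those transforms model. A pair signature
is a Cox linear predictor over such indicators,

    Sum       = sum_i  coef_i * I(A_i|B_i)
    RiskScore = exp(Sum),

with a fixed cutoff separating high from low risk. The package ships the
published IPRP instance of this family (10 pairs over 15 genes, cutoff
0.684) as a frozen constant, and implements the machinery to build,
score and evaluate such signatures from scratch.

## Signature construction cascade

`build_signature` reproduces the standard selection pipeline:

1. **Consensus clustering** of the training cohort on each of two curated
   gene sets (pyroptosis-related and immune-related in the intended
   application). Gene rows are z-scored; for each candidate k the samples
   are subsampled (80%, 100 resamples by default) and k-means-clustered;
   the consensus matrix records co-clustering frequencies among
   co-sampled pairs. k is selected from the relative increase of the area
   under the consensus CDF (threshold 0.1, overridable); final labels
   come from average-linkage hierarchical clustering of the consensus
   matrix. The inner clusterer, resample count and subsample fraction are
   conventional consensus-clustering defaults; nothing in the method
   depends on them strongly, and all are exposed as parameters.
2. **Survival labelling**: the cluster with the largest restricted-mean
   survival time (restricted at the largest observed time) is labelled
   favourable, with a one-vs-rest log-rank test reported; a p-value near
   1 flags a tie. Patients favourable under both gene sets form the FF
   group, unfavourable under both the UU group.
3. **DEG screen** FF vs UU: per-gene two-sided Wilcoxon rank-sum test
   (normal approximation with tie correction), Benjamini-Hochberg
   correction across all genes, then the gate |log2FC| > 1 and
   FDR < 0.001. log2FC is the difference of group means on the already
   log-scale matrix (the choice of means over medians is ours).
4. **Univariate Cox screen** of the DEGs; features are kept at
   BH-adjusted Wald p < 0.05 (the correction is applied before the gate).
5. **Gene-level LASSO-Cox**: coordinate-descent L1 path
   (scikit-survival), with the penalty chosen at the minimum
   cross-validated deviance, where the held-out deviance is minus twice
   the Breslow partial log-likelihood of the held-out fold at the
   training-fold coefficients (10 folds, seeded). The alternative
   one-standard-error rule is deliberately not used; minimum deviance is
   the default in the reference R implementation of glmnet's `cv.glmnet`
   selection when `lambda.min` is taken.
6. **Pairing**: all n(n-1)/2 pairs of the selected genes, canonical
   lexicographic orientation (the downstream Cox signs absorb
   orientation), one-hot encoding, and the prevalence filter keeping
   pairs whose "1" frequency lies in [0.2, 0.8] inclusive.
7. **Pair-level LASSO-Cox**, as in step 5.
8. **Bidirectional stepwise Cox** (the "both" option): starting from the
   full LASSO-selected set, at each step the single add or drop move with
   the best AIC improvement is applied until none improves. Perfectly
   collinear candidates are pre-dropped; a non-converging fit falls back
   to a tiny ridge penalty (1e-4) and, failing that, drops the offending
   feature.
9. The **cutoff** is the median training RiskScore.

Each stage can only shrink the candidate set; a stage that empties it
raises an error naming the stage. The stage sizes are recorded in the
model's provenance.

## Risk scoring

`score_cohort` encodes the model's pairs (orientations preserved exactly
as specified, e.g. the published model contains both TAF1C|ACSL3 and
ACSL3|CRTAP), computes Sum and RiskScore = exp(Sum), and stratifies at
the cutoff. A score exactly at the cutoff is low risk — the high-risk
call requires strictly exceeding the cutoff, which keeps it conservative;
the tie case is otherwise undefined in the signature family. Ties in
expression map to indicator 0 with no epsilon tolerance: floating-point
equality is taken literally, which matters only for discrete data (e.g.
rank-transformed or count data). Gene symbols are matched
case-sensitively; alias resolution is out of scope.

## Survival evaluation

Kaplan-Meier estimation and the unweighted log-rank test wrap lifelines.
The time-dependent ROC at horizon t uses the cumulative-case /
dynamic-control definition with inverse-probability-of-censoring weights
from the Kaplan-Meier estimator of the censoring distribution (cases
weighted by 1/G(T-), controls by 1/G(t)); tied scores count 1/2. This
estimator is implemented in the package and cross-checked in the test
suite against scikit-survival's independent implementation to 1e-8.
The permutation test permutes scores across samples (case/control status
and weights are score-free and precomputed) and reports the add-one
p-value (1 + #{AUC_perm >= AUC_obs}) / (n_perm + 1). Harrell's C is
computed for risk scores (higher score, shorter survival). The
cross-cohort robustness check is a one-way ANOVA of scores on cohort
label — a diagnostic of distributional stability, not a formal test.

## Nomogram

`build_nomogram` re-parameterizes a fitted multivariate Cox model (age,
prior non-myeloid malignancy, ethnicity, risk score by default; ELN2017
can be added as an optional factor) onto the conventional 0–100 point
scale: each factor's contribution beta*x over its observed training range
is mapped linearly, with the widest-range factor spanning exactly 0–100.
Points are kept continuous rather than rounded to integers, so the
mapping is exact: total points convert back to the linear predictor and
survival follows from S_ref(t)^exp(lp - lp_ref), with the reference
survival taken from the Cox model's own Breslow-baseline prediction at an
explicit all-minimum-contribution reference patient. Consequently
nomogram predictions equal the Cox model's predictions to floating-point
accuracy (verified to < 1e-8 on synthetic patients); a rounded-integer
presentation would trade that exactness for readability and is not
implemented. Out-of-range continuous inputs are clamped with a warning;
missing factors and unknown categorical levels are errors. Missing
clinical data are handled by complete-case analysis with logged counts.

## Synthetic data generator

The generator emulates the multi-cohort regime the workflow assumes; it
defines the study conditions for all simulation-based tests.

* **Survival**: Weibull-baseline proportional hazards, inverse-transform
  sampling; default shape 1.2, scale 1500 days. Censoring is an
  independent exponential whose rate is solved (Brent) so the expected
  censored fraction equals `censor_rate` (default 0.3).
* **Planted pairs**: by default 3 disjoint gene pairs with log hazard
  ratios (+1.0, -1.0, +0.9) and target prevalence 0.5. The ordering of a
  pair is driven by a latent Bernoulli indicator; the two genes sit at
  baseline +- separation/2 (separation 2.5, noise sd 0.3 on a log2-like
  scale), so the encoded indicator equals the latent one except with
  probability ~2e-9 per sample.
* **Severity coupling**: a per-patient latent u ~ Uniform(0,1) tilts each
  indicator's Bernoulli probability by +-0.8*(u - 1/2) (sign matching the
  coefficient) and drives membership in two 3-cluster gene sets (15 genes
  each, centroids drawn once per seed with sd 2.0, within-cluster noise
  sd 1.0, cluster labels are noisy tertiles of u). This gives the
  clustering -> FF/UU -> DEG path a real signal while keeping each
  indicator's marginal prevalence at its target.
* **Clinical covariates**: age ~ N(60, 10) (log hazard +0.03/year around
  60), prior malignancy ~ Bernoulli(0.15) (log HR +0.5), a 3-level
  ethnicity factor, and an ELN2017-like class derived from u tertiles.
* **Batch effects**: per-cohort strictly monotone transforms — affine
  with positive slope, optionally composed with exp(x/4), x^3, or a
  within-sample rank transform. Defaults give 5 cohorts of 250 samples
  with distinct transforms, approximating the scale of a five-cohort,
  ~1300-patient study.

What the generator does **not** emulate: real gene-gene covariance,
real AML gene symbols or pathway structure, platform-specific noise
(probe saturation, count overdispersion), treatment effects, or
competing risks. Passing the simulation suites therefore demonstrates
the correctness and batch-invariance of the machinery under a correctly
specified proportional-hazards world, not clinical validity on real
cohorts — the frozen published model's structural checks are exact, but
its clinical performance figures require the original patient cohorts.

## Problem sizes and numerical choices

Simulation-based checks use n = 500–1000 training samples and 2 held-out
cohorts for recovery experiments, 100 consensus resamples, 10 CV folds,
199–1000 permutations, and 20 random monotone transforms for the
invariance suite; these sizes give stable results at interactive
runtimes. Cox fits use lifelines defaults (Efron tie handling); the
stepwise criterion is the partial-likelihood AIC; all randomness flows
from explicit integer seeds through `numpy.random.SeedSequence` and every
simulation is reproducible bit-for-bit from its seed.

## Known limitations

* The cascade's cluster-number selection assumes the consensus-CDF
  delta-area heuristic; pathological data with no cluster structure fall
  back to the smallest k.
* The prevalence filter's inclusive boundaries ([0.2, 0.8]) follow the
  deletion rule "below 0.2 or above 0.8"; data sitting exactly on the
  boundary are kept.
* The LASSO stage inherits coordinate-descent path defaults
  (alpha_min_ratio 0.01, 50 alphas); extremely correlated designs may
  select arbitrarily among near-duplicates, which the later stepwise
  stage resolves by AIC.
* Expression input is assumed pre-processed and log-scale by convention;
  the package applies no normalisation of its own (the encoding makes it
  unnecessary for scoring, but the DEG log2FC gate does interpret the
  matrix scale literally).
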