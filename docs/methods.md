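# Methods

`revcon` re-creates, on fully synthetic data, a personalised
drug-repositioning analysis for bulk tumour RNA-seq: per-sample
differential-expression signatures are scored for *reversal* against
drug-perturbation signatures, and the per-sample approach is benchmarked
against group/subtype aggregation with a negative-binomial simulation null.
This note records the models, the parameter choices that matter, and the
limits of what the synthetic experiments demonstrate.

## Count model and tumour signatures

Counts for gene *g* in sample *i* follow a negative binomial (NB) with mean
μ_gi and variance μ + φμ² (size = 1/φ; φ = 0 is the Poisson limit), with a
log-linear mean

    log μ_gi = x_i' β_g + o_i,

where o_i = log(library size of sample i). Coefficients are fit by
iteratively reweighted least squares (IRLS) with working weights
μ/(1 + φμ), vectorised across genes; iteration starts from a least-squares
fit to log(y + 0.5) − o (deterministic) and stops when the relative
deviance change falls below 1e-8 or after 50 iterations (a per-gene
convergence flag is kept). Linear predictors are clipped at ±30 to keep
exp() finite; genes with all-zero counts inside a contrast are reported
with log2FC 0 and p 1.

A **single common dispersion** is estimated once per cohort by maximising
the profile log-likelihood summed over genes (β re-fit at every candidate
φ) on a log-spaced grid over [1e-4, 10] refined by golden section, using a
tissue-type (tumour/normal) design. The common φ is then *fixed* for every
contrast: a contrast with a single tumour sample carries no information
about its own dispersion, and a shared φ keeps the per-sample
likelihood-ratio tests well defined. Consequence worth knowing: planted
biological heterogeneity (subtype/private programs) that the tissue design
cannot explain is absorbed into φ, so the estimate sits above the
generative "technical" dispersion and per-sample power falls accordingly.
This is a property of the method, not a defect of the estimator — on
homogeneous data the estimator recovers φ to ±0.05 at 500 genes × 50
samples.

Four signature families are produced, each gene carrying (log2FC = β/ln 2
for the contrast coefficient, LRT p against χ²(1), Benjamini–Hochberg FDR
computed within the signature):

* **group** — all tumours vs all normals;
* **subtype** — each subtype's tumours vs all normals;
* **sample** — each single tumour vs all normals;
* **normal control** — each normal vs the other normals (the empirical
  false-positive yardstick for the per-sample signatures).

One-vs-rest contrasts are solved in closed form: the indicator
coefficient's score equation forces the contrasted sample's fitted mean
onto its observed count (zero deviance contribution), so the full model
reduces to the background's intercept-only fit and the LRT statistic to
`deviance(reduced) − deviance(background)`. This is the exact MLE (verified
against the general IRLS fitter to 1e-6) and makes 10⁴-batch simulation
studies affordable.

## Drug signatures

Each drug's experiments — all cell lines, durations and batches pooled —
are modelled per gene by OLS with drug concentration as a *linear*
covariate (0 = vehicle control; log-concentration is deliberately not the
default) and cell line, duration and batch as categorical covariates.
Reference levels are the lexicographically first level; single-level blocks
are dropped; the duration block enters only when more than one distinct
duration is present (the narrower reading of an ambiguous rule — documented
here, applied consistently). Drugs with no control column, no treated
column, a rank-deficient design, or zero residual df are UNPROCESSABLE and
excluded with a logged count.

Residual variances are moderated with the scaled-F empirical-Bayes model:
hyperparameters (d0, s0²) come from moment-matching the mean and variance
of log s² through digamma/trigamma identities (trigamma inverted by
Newton), d0 clamped to [0.1, 1e6] before the d0 = ∞ branch (taken when the
method-of-moments variance is non-positive, i.e. variances look
exchangeable). Posterior variance is (d0·s0² + df·s²)/(d0 + df) and the
moderated t uses d0 + df degrees of freedom. Signature quality is **%DEG**:
the percentage of genes under 50% FDR.

## Connectivity

A tumour query is the signature thresholded at FDR < 1%, split into up and
down sets weighted by |log2FC| (weight exponent 1; genes absent from the
drug platform are dropped, not zero-weighted; pairs with fewer than 5
shared query genes are UNSCORABLE and excluded from every denominator).
Drug genes are ranked by decreasing moderated t, ties broken by gene id.
Each set's enrichment score (ES) is the signed extremum of the weighted
Kolmogorov–Smirnov running sum (hit j adds w_j/Σw, miss subtracts
1/(N−N_hit)); when the positive and negative extrema tie in magnitude the
positive one is reported. The two sets combine as

    score = (es_up − es_down)/2  if the signs differ or one is 0,  else 0,

so score < 0 means the drug opposes the signature. Significance comes from
resampling gene labels: random disjoint up/down sets of the observed sizes
(weights retained) on the drug's gene universe, two-sided
p = (1 + #{|score_perm| ≥ |score|})/(n_perm + 1). **Negative enrichment**
is score < 0 with p < 0.05. Per-sample queries use n_perm = 1000 by
default; group/subtype queries use 1000 × (number of tumour samples). Every
permutation stream derives from the global seed via a CRC-based derivation
keyed by (sample, drug), so results are independent of iteration order.

A consequence of the combination rule: the *combined* score has an atom at
0 (same-sign pairs), hence its null p-value distribution has an atom at 1
and is uniform only conditionally. Calibration of the permutation
machinery is therefore asserted on single-set queries, where the score is
continuous and the null p is uniform outright.

## Drug-level summaries

Per drug: `neg_freq`, the fraction of scored samples negatively enriched.
Its empirical cumulative P compares against "statistically empty" drug
signatures — drugs whose DEG count falls below the 95th percentile of
chance DEG counts, obtained by Monte Carlo (uniform p-values → BH → count
below 50% FDR, 10,000 replicates). BH FDR is then applied *within each
decile* of %DEG (deciles by rank, ties broken by drug id). Quality
correlations use tie-aware Spearman rank correlation.

Gene directionality profiles report, per group-signature gene (FDR < 1%),
how often sample signatures include it (at FDR 1% or 50%) and how often
with the group's sign. Replicate consistency bins replicate score pairs by
the first analysis' P into [0.01, 0.1), [0.001, 0.01) and < 0.001 and
reports the same-sign fraction; a technical replicate is a re-measurement
of the same cohort — new NB noise on the same planted truth
(`CohortConfig.count_noise_seed`) — pushed through the entire analysis.
Re-running with only a new permutation seed would leave scores
bit-identical and the comparison vacuous.

## Simulation null

The fitted group (or subtype) model becomes a generator: per-gene mean at
unit depth μ_g = exp(x'β) with x the tumour condition, size = 1/φ (Poisson
flag at φ = 0), and the observed tumour library sizes as an empirical depth
pool. Unconverged genes fall back to the observed depth-corrected group
mean, flagged. Batches resample depths with replacement, draw NB counts,
and re-run the *full* per-sample pipeline against the real normal samples
(signatures are re-fit per batch; φ stays at the cohort estimate). Per-drug
2.5%/97.5% interval endpoints use the `lower`/`higher` percentile methods,
so two batches give exactly min/max and the interval is never
anti-conservatively narrowed; fold ratios are observed/endpoint. Per-batch
seeds derive from (seed, batch id). The default budget is 200 batches of 50
samples — a desk-scale choice; the batch loop costs a few tens of
milliseconds per batch at a few hundred genes, so larger budgets are a
configuration change, not a code change. Batches use n_perm = 39, the
smallest budget that can resolve P < 0.05 under the +1 rule; observed
counts are computed with the same budget so the comparison is like for
like.

## Synthetic data: what it emulates and what it does not

The cohort generator plants three program layers — cohort-wide (group),
per-subtype, and per-sample private — with fixed-magnitude effects
(`effect_log2fc_sd`, default 1.0 log2 units) of random sign, on genes drawn
without replacement per program (programs may overlap). Baseline means are
log-normal (meanlog 4, sdlog 1.5) to mimic RNA-seq dynamic range; library
size factors are log-uniform on [0.5, 2]; counts are NB with common φ
(default 0.1). Stages 1–4 can scale the private fraction
(`stage_private_gradient`), and a fraction of tumours can arrive as two
samples per patient (shared subtype/stage, independent private programs).
A reversal drug's target program is the target scope's *full* expression
profile — group plus its subtype plus its private effects, summed per gene,
exactly as they sum in the count means — and its per-gene concentration
effect is −k times that profile; opposing only the private records would
make reversal drugs undetectable behind the shared programs that dominate
every query. Drug expression adds gene-level cell line/batch/duration
offsets (shared panel-wide) and Gaussian noise (default SD 0.5); default
concentrations (0, 1, 10) with two durations, three cell lines, two
batches. These defaults are free parameters of the synthetic study, not
estimates of any real perturbation database.

Not emulated: landmark-gene inference (measured-vs-imputed structure),
probe-level microarray artefacts, cross-platform batch effects,
GC/length-dependent biases within the count model, and correlated gene
modules (genes are independent given their program memberships). Passing
tests therefore demonstrate the *statistical machinery* — calibration,
recovery, discrimination, coverage — under the model's own assumptions;
they do not certify performance on real tumour/perturbation data, where
effect sizes are smaller, correlated, and contaminated by technical
structure.

## Numerical and design choices

* "At least a sixth of all samples" uses ceil; "above 0.5 CPM" is strict.
  The filter pools tumour and normal samples.
* Between-sample depth normalization scales each column's upper quartile of
  nonzero reads-per-kilobase onto the *median of per-column upper
  quartiles*. A flattened-matrix quantile violates the identity and
  scale-invariance properties one wants from the normalizer purely through
  percentile interpolation; the median-of-quartiles target satisfies both
  and the fixed point (equal output quartiles) exactly. A full-quantile
  variant is available by flag. Count models consume raw counts with
  offsets; normalized values feed diagnostics only.
* FDR is computed within each signature separately, never pooled across
  the per-sample signatures.
* Empirical P-values use the +1 convention throughout (never exactly 0).
* The "+1"/percentile/tie-break conventions, the ES combination rule and
  the d0 clamp are contracts of this package: the quantities they decide
  are reported to users, so they are fixed and documented rather than
  left to library defaults.

## Problem sizes

The bundled analysis runs a 1,500-gene, 30-tumour/20-normal cohort against
40 drugs; the test suite uses 200–1,000 genes, 5–32 tumours, and up to 100
drugs, with 10,000 total simulation batches in the coverage study (50
repetitions × 200 batches × 20 samples). These sizes were chosen so the
whole study runs on one CPU in minutes while every statistical property
under test retains enough power to fail visibly if the implementation is
wrong.

## Known limitations

* Common dispersion only (no tagwise/trended shrinkage, no quasi-likelihood
  F-tests); per-sample p-values are anti-conservative when heterogeneity
  inflates gene-specific variance non-uniformly.
* Per-sample contrasts have one observation in the contrast cell: power for
  genes with low baseline expression is intrinsically poor, and recovery
  claims are conditioned on adequately expressed genes.
* The permutation null resamples gene labels, not samples; gene–gene
  correlation in real data would make it anti-conservative.
* Alternative connectivity scorers (cosine, XSum, weighted-sum variants)
  are out of scope.
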