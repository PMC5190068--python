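# Methods

`recursig` implements a cross-cohort recurrence-signature analysis for
optimally debulked serous ovarian carcinoma (SOC), together with a
synthetic-data generator that reproduces the statistical structure the
analysis assumes, so that every stage is testable without access to the
original cohorts.

## Cohort preparation

A cohort is a genes x samples expression matrix plus per-sample clinical
records. Eligibility keeps samples that (a) were optimally debulked
(residual disease <= 1 cm), (b) have a known recurrence status, and (c) if
recurrent, relapsed strictly more than `min_recurrence_days` (default 90)
after the end of first-line therapy; relapse at exactly the threshold is
excluded. Expression is then z-scored per gene with the sample SD (ddof=1);
zero-variance rows are left at 0 and flagged. Duplicate gene rows are
collapsed by keeping the highest-variance row — deterministic and the usual
probe-collapse convention. Real curated collections additionally remove
low-correlation and duplicated samples; that step has no published
algorithmic definition and is deliberately not implemented — callers
should apply their own sample QC before loading.

## SNR screening

For each gene, SNR = |mu1 - mu2| / (sigma1 + sigma2) between the
recurrence classes (group 1 = recurrence), with sample SDs and no variance
floor. Genes whose two SDs are both zero are flagged degenerate and
excluded rather than given infinite scores. Ranking is by unsigned SNR;
genes tied with the k-th rank are all kept so that gene-name ordering never
decides biology. The cross-cohort signature is the intersection of the
per-cohort top-k sets (default k = 2000), returned alphabetically. SNR is
treated as a pure ranking statistic; no multiplicity calibration is
attached to it.

## Min-p cutpoints and status calling

A marker's cutpoint is learned on one reference cohort: candidates are the
midpoints between consecutive distinct values, excluding those that leave
less than `min_group_fraction` (default 0.10, to avoid degenerate tail
splits) of samples on either side; each candidate is scored by the
uncorrected 2x2 Pearson chi-square p of the dichotomized marker against
binary recurrence, and the arg-min is returned. Ties are compared on the
chi-square statistic with 1e-9 relative tolerance and resolved toward the
smaller threshold. Values equal to the threshold are called "high". The
minimized p is optimistically biased (no correction over the candidate
scan) and is reported as a selection criterion, not a test. Cutpoints are
learned once on the reference cohort and applied to all cohorts on the
z-score scale. Two markers' calls combine into the 4-level crossed status
(-)(-), (+)(-), (-)(+), (+)(+), with a 2-level collapse of (-)(-) versus
the rest.

Min-p thresholds are maximally selected statistics and converge at a
cube-root rate: at n = 1000 with two components separated by 2 within-SDs
the estimator is unbiased with SD ~0.09 (30-seed simulation). Recovery
claims are therefore evaluated on the median over seeds.

## Association statistics

* Pearson chi-square without continuity correction (the published
  contingency statistics only reproduce with the uncorrected statistic).
* Monte-Carlo chi-square p from tables resampled with fixed margins
  (Patefield sampling), p = (1 + exceedances) / (B + 1), never zero.
* Fisher's exact test: two-sided p; odds ratio as the conditional MLE with
  the exact 95% CI (this is the estimator whose "Inf" point estimates come
  with finite lower confidence bounds on tables with empty cells).
* K-sample location test on the one-way ANOVA F statistic, either against
  the F reference distribution or by label permutation.
* TukeyHSD pairwise comparisons followed by Benjamini-Hochberg adjustment
  across the comparison list. The double adjustment is unusual but is the
  documented procedure for the expression-by-CNA comparisons; it is applied
  as stated.
* OLS with a two-sided t test on the slope.

## Survival models

Recurrence-free survival measures days from the end of first-line therapy;
recurrent samples contribute events, non-recurrent samples are censored at
last follow-up. Kaplan-Meier uses the product-limit estimator with
Greenwood standard errors; group comparison is the Mantel-Haenszel
log-rank test. Cox proportional-hazards fits use Efron tie handling
(lifelines), Wald CIs, and flag non-convergence and near-separation
(|beta| > 20) instead of reporting silently. Covariate coding, in
particular the reference level of low/high status, is the caller's
explicit choice: published tables that report HR < 1 for a "low/high"
label are consistent with the opposite coding, and the package does not
guess.

## Recurrence classifiers

Classifiers are trained on continuous z-scored expression of the signature
genes: 5 repeats of stratified 10-fold CV with an internal hyperparameter
grid (regularization strength over 7 log-spaced points for margin models),
selection by mean CV AUC, final refit on the full training cohort. The
linear max-margin model is the reference; radial-kernel SVM, random forest
and a small neural network sit behind the same interface. Validation AUC
is the Mann-Whitney rank statistic with ties counted 0.5, and its CI is
DeLong's placement-variance interval truncated to [0, 1]. Because
hyperparameters are chosen by maximizing CV AUC over a grid, the training
CV AUC is mildly optimistic; on permuted labels its 20-seed mean stays
within (0.45, 0.55).

## Interaction subnetwork and axis

Edges with combined score < 600 are dropped (duplicates keep the max
score, self-loops removed). The two-seed subnetwork is the induced
subgraph on the seeds plus all nodes within k = 1 hops of either seed,
restricted to the component containing both — the 1-hop-union reading; a
Steiner-minimal subgraph is a stricter alternative reading and is not what
the decoy-rich published subnetwork shows. The axis is the unweighted
BFS shortest path between the seeds, with equal-length ties resolved to
the lexicographically smallest node sequence. Communities come from greedy
modularity agglomeration on the unweighted subnetwork.

### Bayesian-network direction inference

Per cohort, a linear-Gaussian network over the axis genes is learned by
steepest-ascent hill climbing (add/delete/reverse single edges from the
empty graph, deterministic lexicographic tie-break), scoring each node by
its maximized Gaussian log-likelihood minus a penalty per free parameter
(coefficients + intercept + variance). Two penalties are available:

* `aic` (default; weight 1 per parameter) — the procedure as published,
  used for the per-cohort axis DAGs and the direction consensus;
* `bic` (weight log(n)/2) — the consistent choice for structure-recovery
  experiments.

AIC is deliberately liberal: it admits a spurious edge per variable pair
with probability P(chi2_1 > 2) ~ 0.157, so on 3 independent Gaussians the
empty graph is returned at rate ~0.843^3 ~ 0.60, and a strong 3-variable
chain's exact skeleton is recovered at ~0.84. Unit tests assert these
rates against binomial bounds from the closed form. High-probability
(>= 90%) skeleton recovery requires a consistent penalty, so recovery
experiments use `bic` (false-add ~0.013, recovery ~0.97); under `bic` the
hill climb also attains the global optimum over all 543 labeled 4-node
DAGs in every tested seed, while AIC's spurious-edge landscape leaves
occasional local optima.

Gaussian scores are identical across Markov-equivalent DAGs, so a single
cohort's edge directions are tie-break artifacts. Each structure therefore
also exposes its skeleton, and the reportable quantity is the cross-cohort
consensus: per unordered pair, directions are tallied over cohorts and the
call is the strict majority among cohorts where the edge is present; ties
and all-absent pairs are undetermined. Activation/inhibition signs are not
inferred. Enrichment of the subnetwork gene set is an upper-tail
hypergeometric test per user-supplied gene set (GMT), BH-adjusted across
sets.

## IHC immunoreactive score

IRS = staining intensity (0-3) x percentage category (1-4), low for 0-6
and high for 8-12; the products 7, 10, 11 are unreachable, so the gap in
the rule is harmless (asserted by a totality test). Two blinded raters'
components are merged by the mean rounded half-up — the adjudication rule
is not published, so this explicit deterministic rule is used and logged.
Cases missing either marker are excluded from crossed grouping.

## Synthetic cohorts

The generator emulates the seven public SOC cohorts the analysis was
designed around: default cohort sizes (305, 156, 37, 77, 17, 120, 126),
recurrence prevalence 0.57, median time to recurrence 450 days, all day
fields offset by 91 days so eligibility filtering is non-destructive
unless requested. Per cohort: recurrence labels are Bernoulli(prevalence);
planted genes are equicorrelated unit Gaussians (default rho 0.5) whose
means shift by delta (default 1) in the recurrence class, so the
population SNR is delta/2; null genes are independent standard Gaussians.
Recurrence times are exponential with the hazard multiplied by
`hazard_ratio_high` (default 2) for samples above the cohort median of the
mean planted expression; non-recurrent samples get exponential censoring
times whose rate follows the competing-exponentials identity for the
requested censoring rate. Reproducibility uses one global seed with
per-cohort substreams (`default_rng([seed, cohort_index])`), so adding a
cohort never reshuffles existing ones.

This construction is a cure-mixture model: only labeled-recurrent samples
ever experience the event. Under such a model the marginal Cox estimand
for the expression-high indicator does not equal the generative hazard
multiplier — long censored follow-up dilutes risk sets and attenuates the
fitted HR (~1.4 for a generative 2 at comparable follow-up), while the
label-expression coupling inflates it (~3 at delta = 1). Hazard-ratio
recovery is therefore assessed on the all-event design
(`recurrence_prevalence = 1`), where the estimand equals the multiplier
and n = 1000 fits land within (1.85, 2.2) across seeds.

CNA states come from thresholding a latent Gaussian correlated with
expression at `cna_coupling` into 5 bins at the 2.5/16/84/97.5% quantiles
(homozygous states rare, as in real marginals); methylation is the
logistic transform of a latent with negative coupling. The interaction
fixture plants the 4-gene chain at scores >= 800, decoy neighbors at
600-1000, and a sub-threshold seed-to-seed shortcut that the score filter
must remove. The IHC generator draws intensity/percentage categories from
thresholded latent risks shifted by `effect` in recurrent cases, with
covariate marginals matching a 127-case cohort.

What the generator does not emulate: platform-specific microarray noise,
batch effects, gene-gene correlation beyond the planted block, informative
censoring, or real STRING topology. Passing recovery tests shows the
estimators work under the stated model, not that the biological findings
replicate on new data; real cohorts are consumed through the same TSV
interfaces ("bring your own data": point the CLI config at per-cohort
expression/clinical TSVs, an edge table and an IHC table to replay every
stage on real inputs).

## Problem sizes and numerics

Simulation-based tests use 7 x 150 samples x 1000 genes (screening
recovery), n = 1000 (Cox, cutpoint, binormal AUC), n = 500 (BN recovery),
and 20-100 seeds per calibration claim. Cox convergence follows lifelines
defaults; BN hill climbing stops when no move improves the score by more
than 1e-12; Fisher oracle comparisons use exhaustive hypergeometric
enumeration. Monte-Carlo p-values carry the +1/+1 correction. Known
limitations: no time-varying covariates or proportional-hazards
diagnostics; no exact unconditional 2x2 tests; enrichment ships no
ontology content (user-supplied GMT only); the min-p procedure reports an
uncorrected minimum p by design.
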