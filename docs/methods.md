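# Methods

## Model

`h2atlas` partitions the SNP heritability of a complex trait across functional
annotation categories.  The phenotype vector y of N individuals is modelled as

    y = X b + g_1 + ... + g_k + e,
    g_i ~ N(0, sigma2_i K_i),   e ~ N(0, sigma2_e I),

where each K_i = W_i W_i' / M_i is the genetic relationship matrix over the
M_i SNPs assigned to annotation component i, with W_i the dosages standardized
by in-sample allele frequency, w = (x - 2p) / sqrt(2p(1-p)) and missing
dosages mean-imputed (w = 0).  Fixed effects X always include an intercept and
optionally principal components and study indicators.

Components are defined by a priority-ordered hierarchy: every SNP belongs to
the *first* component (coding > UTR > promoter > annotation of interest > DHS
> intron > other) whose merged intervals contain its position (BED 0-based,
half-open).  The partition is therefore exhaustive and exclusive, and each
component's share of SNPs is the null expectation for its share of genetic
variance.  The coding-proximal components are retained in every model so that
an annotation's estimate is not inflated by linkage to coding variation.

Reported quantities per component i:

* observed-scale heritability  h2_i = sigma2_i / (sum_j sigma2_j + sigma2_e);
* share of genetic variance    %h2g_i = sigma2_i / sum_genetic sigma2_j, with a
  delta-method standard error using the gradient
  d f / d theta_i = (S - theta_i)/S^2, d f / d theta_j = -theta_i/S^2
  (S the genetic total) and the inverse Average-Information matrix as the
  estimate covariance;
* enrichment Z = (%h2g_i - %SNPs_i) / SE, two-sided normal p-value.  The test
  is two-sided because depletion (e.g. repressed chromatin) is a reportable
  signal;
* for case-control traits, totals transformed to the liability scale,
  h2_liab = h2_obs K^2 (1-K)^2 / (P(1-P) z^2), with prevalence K, sample case
  fraction P and z the standard normal density at the (1-K) quantile.

## Fitting

Restricted maximum likelihood via Average Information (AI-REML).  The
restricted log-likelihood -1/2[log|V| + log|X'V^-1 X| + y'Py] is maximised
with Newton steps using AI_ij = 1/2 y'P K_i P K_j P y, score
s_i = -1/2[tr(P K_i) - y'P K_i P y], guarded by step-halving; iteration starts
from an equal split of the phenotypic variance with one EM burn-in step, which
stabilises the first AI update.  Convergence requires a relative parameter
change below 1e-6 and a likelihood change below 1e-8; the default iteration
cap is 100.

Variance components are constrained non-negative by default (reported 0.0%
components arise this way): a component whose estimate is driven to the
boundary is held at a floor of 1e-8 x var(y) and, when its score points
further downward, removed from the active Newton system for that iteration —
without this active-set treatment the constrained fit crawls near the
boundary.  Whether the published analyses constrained components is not
explicitly documented for this estimator family; both modes are implemented
(`constrain_nonnegative=False` gives the unconstrained fit) and the
constrained mode is the default because reported 0.0% estimates imply it.
The inverse AI matrix at convergence is used as the error covariance of the
estimates, with boundary components' rows retained and flagged: their SEs
should be read as local curvature, not as symmetric confidence intervals.

Degenerate fits (e.g. a single component with K = I, where genetic and
residual variance are not separately identifiable) are detected by the
condition number of the AI matrix (> 1e12) and flagged; the covariance then
falls back to a pseudo-inverse.

## Synthetic cohorts

The simulation framework emulates the study conditions the estimator is
validated under, so that no external genotypes are needed:

* **Genotypes** — unlinked biallelic SNPs, dosage ~ Binomial(2, p), MAF drawn
  from a configurable spectrum (default uniform on [0.01, 0.5]); monomorphic
  draws are resampled.  An optional block-LD generator (equicorrelated latent
  Gaussian within blocks) exists for tagging-loss experiments; by default SNPs
  are unlinked so that estimator correctness is isolated from LD confounding.
* **Annotations** — the genome is tiled into windows holding one SNP each;
  each category receives a disjoint random draw of windows so the exclusive
  per-component SNP fractions match the configured values essentially exactly
  (an `overlap` option adds raw overlaps, which the hierarchy resolves).
  Default fractions: coding 1.8%, UTR 1.9%, promoter 3.4%, focal annotation
  3.22%, DHS 15%, intron 30%, other = remainder.  The first four follow the
  annotation sizes of the genotyped data the estimator was validated against;
  DHS and intron are realistic genome-wide shares chosen once.
* **Phenotypes** — 5,000 causal SNPs by default (500 in the scaled-down
  acceptance studies), drawn uniformly within source components, with
  component counts apportioned so each component's expected share of genetic
  variance matches the configured `causal_source` (variance share, not SNP
  count — the documented resolution of an ambiguity).  Effects are normal on
  standardized genotypes (equal variance per causal SNP; the estimator's own
  assumption) or on raw allele counts (per-SNP variance proportional to
  2p(1-p); the "high-frequency" architecture used as a misspecification
  stress test).  The residual is orthogonalized to the genetic value in-sample
  and both parts rescaled, so realized heritability equals the target exactly
  — this makes recovery tests sharp rather than only unbiased in expectation.
* **Case-control** — liability thresholding at the empirical (1 - prevalence)
  quantile of the realized liability (prevalence default 0.14), then
  subsampling to the requested case fraction.
* **Admixture** — two Balding-Nichols populations: per-SNP population
  frequencies Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral p, per-sample
  admixture proportions, per-haplotype ancestry draws.  The realized per-SNP
  F_ST (Hudson estimator on the true frequencies) is returned so causal
  variants can be sampled from differentiation bins.
* **Platform masking** — column subsetting that hides a configurable fraction
  of SNPs (globally or per component) while the phenotype keeps its full-panel
  causal variants; the induced tagging loss is the object of study.

What the generator does *not* emulate: realistic LD structure, haplotype
phase, imputation uncertainty beyond the INFO-score field, sex chromosomes,
or genuine population stratification confounding.  Passing recovery tests
therefore demonstrates correctness of the estimator under its own assumptions
(typed, unlinked causal variants), not robustness to LD-driven biases in real
data.

## Validation studies and problem sizes

The recovery studies replicate cohorts of N = 1,000 samples and M = 10,000
SNPs with 500 causal variants and h2 = 0.5, 50 replicates each — a deliberate
scale-down of the original protocol (N ≈ 3,000, M ≈ 180,000, 5,000 causals)
that keeps every per-SNP and per-component ratio intact.  Under the null
(causals uniform), the focal component's mean %h2g recovers its SNP share;
with the focal component simulated to carry 50% of genetic variance, the mean
estimate recovers that share.  Standard-error calibration uses 100 replicates
of a reduced two-component fit (N = 500, M = 1,000, causals dense at 50% of
SNPs so that the replicate-to-replicate variance of the *truth* stays small
relative to estimation error).

Recovery studies fit *unconstrained* variance components by default, while
ordinary analyses keep the non-negativity constraint.  The reasons are
statistical: evaluating bias requires the interior estimator (a boundary
constraint turns a mean-zero sampling distribution into a truncated one,
biasing small null components upward — at these sample sizes by roughly one
truncation SD), and only the unconstrained mode has a replicate-to-replicate
SD matching the mean analytic SE, the calibration property the studies are
meant to establish.  Both modes are exposed on every fitting entry point;
the constrained production default is what produces reported 0.0%
components.

One residual artefact remains at this scale: %h2g is a ratio of variance
estimates, so under strong enrichment its mean carries a small upward
Jensen bias (a few points at N = 1,000, shrinking with the squared SE of the
denominator); the recovery criteria absorb it within their Monte-Carlo
bands, and the original validation numbers show the same direction.

## Prediction

Three predictors are compared by sequential-fold cross-validation: (i) a
genetic risk score summing dosage x log odds-ratio over genome-wide
significant SNPs from the training folds, thinned by greedy best-p clumping
to one SNP per 1-Mb window (the clumping rule is anchored at the top SNP;
the published text does not specify one); (ii) the single-component BLUP,
g = sigma2_g K_cross P y over all SNPs; (iii) the multi-component BLUP, the
sum of per-component out-of-sample BLUPs weighted by their component %h2g —
equivalent to an annotation-specific prior on effect-size variance.  A
documented `weights="unit"` switch gives the plain joint multi-component
BLUP, since the published description is ambiguous about the extra
weighting; the literal reading (%h2g weights) is the default.  Accuracy is
the R^2 of phenotype on score plus covariates minus the covariate-only R^2;
joint p-values come from the multiple regression on all predictors at once.
A cross-GRM threshold (default 0.05) can remove training individuals related
to any test individual.

## Numerical choices and edge cases

* Grid/oracle checks: the AI-REML optimum is verified against a brute-force
  50^3 grid over the restricted likelihood on small fixtures, BLUPs against
  the ridge-regression closed form (penalty M sigma2_e / sigma2_g), and
  delta-method SEs against hand-evaluated gradients.
* HWE and missingness tests hard-call dosages at 0.5/1.5 (HWE is undefined on
  fractional dosages); HWE is tested in controls only when case status is
  available.
* Relatedness pruning is greedy by above-threshold pair count (ties: higher
  mean relatedness, then lower index).  Greedy removal is deterministic and
  matches common GREML tooling; it is a 2-approximation of the minimum
  removal set, not an exact minimiser.
* QC filters apply in the listed order (MAF, missingness, HWE, differential
  missingness, INFO); the report records per-filter counts, and order
  invariance is deliberately not assumed.
* Ties in clumping resolve to the lower position; ties in causal-count
  apportionment resolve by largest remainder.
* Empty components are skipped with a warning (a conditional-scan annotation
  fully absorbed by earlier hierarchy slots reports an empty exclusive slot,
  not an error); an all-monomorphic GRM subset, a zero-variance phenotype and
  an infeasible annotation spec raise errors.

The admixed-cohort study (`fst_binned_study`) draws all causal variants from
a chosen quintile of realized per-SNP F_ST and checks that the enrichment
test for a differentiation-agnostic annotation stays null-calibrated.  With
unlinked SNPs the ancestry-mediated drift of the *total* heritability
estimate is small compared with its replicate noise at desk scale, so the
study reports the per-quintile totals without asserting their ordering; the
large drift seen in real admixed data rides on LD, which the generator
deliberately omits.

## Known limitations

Dense N x N linear algebra bounds cohorts to a few thousand samples per fit;
the split-half + inverse-variance meta-analysis mode is the intended route
for larger cohorts.  Binary traits are fitted on the observed 0/1 scale and
transformed afterwards, which is standard but approximate under strong
ascertainment.  The delta-method SE of %h2g is first-order and degrades when
the genetic total is near zero.  The 15-group annotation grouping used in
model selection is configuration supplied by the user, not inferred.
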