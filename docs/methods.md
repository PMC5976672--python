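# Methods

## The pipeline and its assumptions

The package analyses a three-class (control / GD / GO), three-centre
case-control design with two feature blocks per subject: miRNA sequencing
counts and label-free mass-spec protein abundances. Its stages are
normalisation/filtering, ordination, per-feature differential expression,
penalised classification with stability selection, set-algebra combining,
pathway enrichment, and a closed-form power calculation. Matrices are
features-in-rows throughout; per-sample operations are column operations.

### Count model

miRNA counts for one feature follow a negative binomial with mean
`mu = exp(intercept + status + centre + log libsize)` and variance
`mu (1 + phi mu)`. `phi = 0` recovers Poisson. The model assumes the
library-size offset captures all per-sample depth variation and that
status and centre act multiplicatively on abundance. Coefficients are fit
by IRLS at fixed `phi` with step-halving on the log-likelihood.

`phi` is estimated per feature by maximising the Cox–Reid adjusted
profile likelihood, `APL(phi) = l(phi, beta_hat) - 1/2 log det(X' W X)`,
over `log phi` in `[log 1e-6, log 30]` (bounded scalar search, tolerance
0.02 on the log scale; estimates below 2e-6 are reported as exactly 0,
the Poisson boundary). The adjustment matters: the unadjusted profile MLE
is biased low at n = 46, which makes the likelihood-ratio test
anti-conservative. The reduced (no-status) model is fit at the
full model's dispersion so the two likelihoods are properly nested and
the LRT statistic `2 (l_full - l_reduced)` is non-negative by
construction; it is referred to chi-square with df = (#status levels - 1).
Measured under a global-null simulation (2000 features, 3 x 15 samples)
the p < 0.05 share is ~0.05 and p-values pass a KS uniformity check.

### Protein model

Each protein enters a multinomial logit of class on centre and the
(log, loading-normalised) protein value, reference class "control",
maximised with L-BFGS on the analytic gradient; quasi-separated fits are
re-stabilised with a 1e-6 ridge and flagged. Dropping the protein term
gives an LRT with df = K - 1 = 2. The model treats a non-detected value
(encoded 0) as just another covariate value; no imputation.

### Loading normalisation (proteins)

Label-free intensities carry an additive per-sample shift on the log
scale (total protein load, injection volume). Left in place, that shift
correlates *every* protein with any chance imbalance of loading across
groups; in simulation this inflated the per-dataset null p < 0.05 share
to 0.14–0.18. We therefore median-centre detected log abundances per
sample, estimating the shift on proteins detected in *all* samples
(falling back to all detected values when fewer than 10 such proteins
exist) so the estimate is not confounded by per-sample detection
composition. Zeros are untouched. Residual coupling through the
detection pattern itself (missingness is abundance-dependent) remains;
it is a property of treating zeros as values rather than censored data.

### Multiple testing

Storey q-values with pi0 estimated by smoothing `pi0(lambda) =
#{p > lambda} / (m (1 - lambda))` over `lambda = 0.05 ... 0.95` with a
cubic least-squares fit evaluated at `lambda = 0.95`, clipped to
`[1/m, 1]`. Below 100 tests the smoother is unstable and pi0 falls back
to 1 (which makes the estimate coincide with Benjamini–Hochberg); `bh`
is also available explicitly. q-values are enforced monotone in p by the
usual cumulative-minimum construction.

### Classifier

Lasso-penalised multinomial logistic regression in the symmetric
parameterisation, objective `(1/N) NLL + lambda sum_j ||theta_j||_1`
over penalised columns; centre indicators are never penalised. The
solver is a partial-Newton outer loop (per-class quadratic
approximation) with cyclic coordinate descent and soft-thresholding,
warm-started along a 100-point log-spaced grid from the data-derived
`lambda_max` down to `0.01 lambda_max`. Numerical details:

- Feature columns are standardised to mean 0 / variance 1 on whatever
  data the fit receives (training split only, by construction of the
  protocol); constant columns get unit scale and can never activate.
- Fitted probabilities outside `[1e-5, 1 - 1e-5]` are snapped to 0/1
  with a floor weight of 1e-5, so a perfectly fitted observation has
  zero working residual and separation cannot diverge.
- The softmax-invariant directions (intercepts, unpenalised columns) are
  mean-centred across classes every outer iteration; convergence is
  declared when the centred coefficients move less than 1e-4, or when
  the penalised objective is flat to 1e-8 relative (weight-snapping can
  produce limit cycles with numerically identical objectives). Fits
  still oscillating by more than 1e-2 after 100 outer iterations raise.
- KKT conditions at the solution are asserted in the test suite:
  `|grad| <= lambda` for zero coefficients, `|grad| = lambda` for active
  ones, to 5e-4.

`lambda` is chosen by 10-fold stratified cross-validation minimising
mean multinomial deviance (CV-minimum rule, not 1-SE). The resampling
protocol draws a 1/10 test set, tunes on the 9/10, refits, and records
overall accuracy, per-class recall, and the set of features with any
nonzero coefficient; R replicates (default 150) give selection
frequencies. Top-k ranking breaks frequency ties by mean absolute
coefficient, then lexicographic id; never-selected features are never
ranked.

Test splits are simple random draws, not stratified. We originally
stratified them, but stratification biases the protocol's permutation
null *below* chance systematically: with near-balanced classes the
training majority is exactly the class under-represented in the
stratified test set, so a no-signal model scores ~1/(test size). Even
with random splits the permutation null sits below 1/K (test and
training compositions of a fixed finite sample are anti-correlated);
measured permuted-label accuracies are ~0.1–0.2 against a nominal 1/3.
Any reader comparing permuted-label accuracy to 1/K should expect this.
CV folds inside the training set remain stratified — the multinomial
fit needs every class present at these sample sizes.

### Combining, enrichment, power

The combiner evaluates
`(mirDE ∩ mirPRD) ∪ (protDE ∩ protPRD) ∪ (mirprotPRD ∩ (mirDE ∪ protDE))`
literally, deduplicates, and keeps per-feature provenance. Enrichment is
the exact hypergeometric upper tail `P(X >= k)` with the universe
defaulting to all annotated genes; `k = 0` gives p = 1; raw p-values by
default (BH optional). The power formula's denominator is `(ln Delta)^2`;
the two alternative readings of the ambiguously typeset fold-change term
(`ln(Delta^2)` and `(ln Delta^2)^2`) are exposed via a flag but rejected
as defaults — they prescribe n <= 3 per group and cannot produce the
published 4–8 range, which the default reproduces exactly (4/5/7 for
power 0.7/0.8/0.9).

## Synthetic data: what it emulates, what it does not

The generator reproduces the study conditions: 13/14/19 subjects per
group across three centres; ~3025 miRNAs and ~1886 proteins; per-sample
library sizes log-normal around 13.07 million reads with CV 0.23;
protein loading CV 0.35; planted effects of 2-fold (the power section's
Delta) on 10% of features, each shifting GD, GO, or both (random signs);
multiplicative log-normal centre effects (sd 0.1 on the log scale).

Choices the study does not pin down, with rationale:

- **miRNA baseline abundances** are log-uniform over relative abundances
  1e-8–1e-2 (spanning the dynamic range of small-RNA libraries), then
  normalised; dispersion `phi` is uniform on [0.05, 0.5], a typical
  biological range for blood small-RNA-seq.
- **Protein log-scale sd is 0.34**, the ln-scale equivalent of the
  study's printed between-sample CV of 0.35 for proteins — the same
  sigma its power formula uses, which keeps the generator consistent
  with the power-consistency checks in the test suite.
- **Non-detection is left-censoring at a limit of detection** placed at
  the `protein_dropout` (default 0.3) quantile of the baseline abundance
  range, with 0.5 nat of per-cell detection jitter. Low-abundance
  proteins drop out preferentially — the actual mass-spec missingness
  mechanism — which reproduces the strong attrition of the
  detected-in-more-than-two-samples filter while keeping well-expressed
  proteins nearly complete. (A uniform per-cell dropout was considered
  and rejected: it makes every detected protein column bimodal, unlike
  any real panel.)

Not emulated: feature-feature correlation (co-expression, shared
pathways), batch effects beyond a centre shift, count compositionality
from a few dominant features, heavy-tailed protein noise, and
missingness that is informative about class beyond the planted effect.
Passing tests therefore show the machinery is correct and calibrated
under the stated generative model, not that real GD/GO data would yield
the same discovery rates.

## Problem sizes used in the automated checks

The checks run at desk scale, chosen so the full suite completes in
minutes: the global-null calibration uses 2000 filtered features at
3 x 15 samples; the end-to-end recovery run uses 400 miRNAs + 200
proteins, 10% planted, 15 per group, with R = 30 resampling replicates
(the protocol's structure is unchanged; R only controls the precision of
selection frequencies); solver and geometry oracles use tens of samples.
Recovery is scored over *detectable* planted features — those passing
the expression filters — because features the design filters out before
any model runs cannot be discovered by any method; about a sixth of
planted features draw baseline abundances below the filter at these
sizes.

## Known limitations

- The top-20 predictor sets cap the combined list: the lasso keeps only
  a sparse predictive subset of the truly differential features (once
  classes separate, additional true features do not reduce CV deviance),
  so the combiner's recall saturates near 50–60% of detectable planted
  features even when differential expression alone recovers ~80%.
- The per-protein multinomial LRT treats zeros as values; residual
  abundance-dependent missingness couples proteins near the detection
  limit to sample loading.
- Storey's pi0 smoother is noisy below a few hundred tests (hence the
  BH fallback), and per-dataset realised false-positive shares vary
  more than the nominal level because tests within one dataset share
  the design and sample-level noise.
- The resampling protocol's permutation null is below 1/K (see above);
  accuracy comparisons against chance should use a permutation
  reference, not 1/K.
- Eq-style log transformation maps both raw 0 and raw 1 to 0; a warning
  is emitted when abundances <= 1 occur (real mass-spec intensities are
  orders of magnitude larger).
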