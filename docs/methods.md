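# Methods

## The model

`ordlcga` fits latent-class growth models to a 4-category ordinal outcome
observed at up to five discretized waves. Each class *c* carries a
free-loading growth curve `eta_ct = alpha_c + beta_c * lambda_t` on a
continuous latent-response scale, with `lambda_1 = 0` and `lambda_5 = 1`
fixed for every class (so `beta_c` is the baseline-to-endpoint change and
the three interior loadings shape the path between the endpoints, including
non-monotone shapes when loadings leave [0, 1]). The observed category is
the latent response plus a standard logistic deviation, cut at three
thresholds shared across classes and waves — an ordered-logit measurement
model. A probit link is not provided; the logit is the conventional default
for categorical outcomes under maximum likelihood in this model family, and
nothing downstream depends on the link beyond the threshold scale.

Within-class growth-factor variances are fixed at zero (an LCGA rather than
a full growth mixture): with sparse data — here a mean of ~2.1 assessments
per person — free within-class variances are empirically under-identified,
and zero variance makes waves conditionally independent given class, so
person-level likelihoods are products of per-wave category probabilities
and missing waves marginalize out analytically (valid under MAR).

### Identification

Free intercepts and free thresholds are jointly location-unidentified:
adding a constant to every `alpha_c` and every `tau_k` leaves the
likelihood unchanged (this invariance is asserted in the tests). Estimation
therefore anchors the middle threshold `tau_2` at a fixed value, 0 by
default. The published parameterization this package ships as its default
generative scenario uses its own location (`tau_2 = -35.02`); `MixtureSpec.
shifted()` re-expresses parameters in any anchor. Information criteria use
the nominal parameter count `p = 6K + 2` (per class: intercept, slope,
three free loadings; plus three thresholds and K−1 proportions), matching
the convention of the published fit-statistic table rather than counting
the anchor.

A further practical identification limit is worth knowing: when a class's
linear predictor is far outside the threshold range (the default scenario's
largest class sits ~70 logit units below the lowest threshold at interior
waves), its category probabilities saturate and its interior loadings
become empirically flat — any sufficiently extreme value fits equally well.
Class proportions and trajectory shapes remain well determined; the
recovery tests therefore check loadings only for classes whose predictors
stay in the identifiable range, and proportions for all classes.

## Estimation

EM on pattern-collapsed data. The E-step reduces to a (K × 5 × 4) table of
posterior-weighted category counts, which makes the M-step cost independent
of N; the M-step maximizes the expected complete-data log likelihood over
all growth parameters and the two free thresholds jointly with L-BFGS-B and
an analytic gradient, computed with saturation-proof log-probability and
gradient-ratio formulas (interior categories via
`log_expit(b) + log_expit(-a) + log1p(-exp(a-b))`). A generalized M-step
that cannot decrease Q guarantees monotone observed-data log likelihood,
which the tests assert iteration by iteration.

Defaults: 50 seeded random starts run for 25 EM iterations, the best 20
run to convergence (relative log-likelihood change < 1e-8, max 500
iterations). A start is seeded by k-means on jittered wave-by-wave category
profiles, thresholds from marginal category frequencies, growth curves from
per-class mean categories — and then one complete-data M-step under the
hard partition, which lets starts reach widely separated solutions in a
single move (without this, starts stall in a compressed local optimum
~1,000 log-likelihood units below the global one on the default scenario).
Starts converging with any class proportion below 0.5/N are discarded as
spurious; the count of starts replicating the best log likelihood (within
0.01) is a first-class output, since non-replication is the working
criterion for rejecting an unstable solution. All randomness flows from one
user seed. Parameter bounds (|alpha|, |beta| ≤ 80, loadings ±30, thresholds
within ±40 of the anchor, gaps ≥ 0.1) keep unidentified directions from
wandering without constraining identifiable solutions.

Standard errors, when requested, come from the observed information matrix:
a central-difference Hessian of the analytic score (via the EM identity
that the observed score equals the Q-gradient at the current parameters),
with proportions parameterized as logits. Sandwich-type robust standard
errors are not implemented.

## Class enumeration

`enumerate_classes` fits K = 1..K_max sequentially, adding one warm start
per K that splits the previous solution's largest class — the practical
device for aiding convergence at larger K. The table reports BIC
(`-2LL + p ln N`), CAIC (`-2LL + p(ln N + 1)`), AWE (`-2LL + 2p(ln N +
1.5)`), the approximate Bayes factor `exp(SIC_k − SIC_{k+1})` with `SIC =
-BIC/2`, the approximate correct-model probability cmP_A (softmax of SIC
over a candidate set, max-shifted so ΔBIC up to 1e6 cannot overflow),
relative entropy `E_K = 1 − mean Shannon entropy / ln K`, per-K deltas for
elbow reading, and convergence/replication flags. The recommendation
(smallest BIC among replicated, converged solutions) is advisory: final
selection in this model family legitimately blends fit statistics with
parsimony and interpretability. Likelihood-ratio-based enumeration tests
(LMR, bootstrap) are not implemented.

## 3-step auxiliary analysis

Step 1 is the unconditional fit; step 2 assigns modal classes and computes
the average-posterior classification-error matrix `q_sc = P(modal s | true
c)` (probabilities floored at 1e-12 before logging; an empty modal class
leaves sentinel logits and a warning). Step 3 fixes `q` and estimates
either a multinomial-logistic model of true class on covariates (direct
maximization with analytic gradient plus a Newton polish; Wald inference
from the observed-information covariance) or a normal distal-outcome model
`Y | C = c ~ N(mu_c, sigma_c^2)` by EM, with missing outcomes contributing
through the indicator only. When classification is perfect, both reduce
exactly to ordinary analyses of the modal labels — the oracle used in the
tests — and when it is not, the correction undoes the attenuation that
naive modal regression suffers (asserted as a directional property).

Contrasts re-reference the multinomial fit by coefficient differencing with
covariances from the full fit. Predictor screening runs one candidate at a
time and retains those with P < .01 on either focal contrast; screened-in
variables are never trimmed, and no multiplicity correction is applied
beyond that threshold. Continuous predictors other than age and sleep hours
are divided by their analysis-sample baseline SD before entering, so odds
ratios read per-SD. With multiply imputed predictors, step 3 runs per
imputation and pools by Rubin's rules.

## Missing-data machinery

Three mechanisms are addressed. Design bucketing and wave sparsity are
handled inside the likelihood (analytic marginalization, tested against
brute-force summation over missing categories). Assessment-count
heterogeneity is diagnosed with a logistic regression of the 3-or-more-
assessments indicator (or a per-wave response indicator) on all baseline
covariates; covariates it flags can be fed to `sensitivity_refit`, which
replaces the mixture proportions with a multinomial-logistic prior
`pi_c(x)` (a concomitant-variable model estimated inside EM) and reports
per-class proportion deltas against the unconditional fit — near-zero
deltas indicate the class structure is robust to that mechanism. Item-level
predictor gaps are multiply imputed (default m = 10) by chained equations
using predictive mean matching (statsmodels MICE) with columns visited in
ascending missingness order after 10 burn-in cycles; PMM draws observed
donor values, so binary and categorical codes remain valid without
per-type model switching. Rubin pooling uses the standard total-variance
and degrees-of-freedom formulas. MNAR/pattern-mixture models are out of
scope; everything assumes MAR.

## Synthetic cohort generator

The generator emulates the structure of the motivating web-based HRA
cohort (N = 22,963), with every default traceable to a published table via
`ordlcga.reference.PROVENANCE`:

- **Trajectories.** Classes drawn from the model-estimated proportions
  (63.66 / 18.65 / 4.69 / 8.05 / 4.96 %, renormalized from their printed
  100.01 % total); categories drawn by cutting logistic deviations around
  the published class curves at the published thresholds.
- **Covariates.** Class-conditional draws from the published descriptive
  tables. Only class means are published for continuous covariates, so the
  full-sample SD is reused within class (slightly overdispersed);
  covariates are independent within class because no covariance structure
  is published. Physical activity's 0/1 summary is generated as Bernoulli.
- **Distal outcome.** Normal with class means reconstructed from the
  published end-of-study mean differences, whose three published effect
  sizes jointly imply a pooled SD of ~16.4; the unpublished minimal-class
  mean is set to 5.0 (a typical low impairment on the 0–100 scale). Values
  are not clipped to [0, 100], keeping the normal distal model exact at the
  cost of occasional out-of-range draws.
- **Missingness.** Baseline is always observed. The number of post-baseline
  assessments is 1 with probability 0.91 (from the 9 % three-plus-wave
  figure) and otherwise follows a truncated geometric on {2, 3, 4} whose
  ratio is solved (brentq) so the mean total is exactly 2.10. Waves are
  placed by weighted sampling without replacement with propensities
  (0.2655, 0.21, 0.1645, 0.46): the last two are the published wave-4/5
  response rates, the first two are interpolated so the marginals sum to
  the calibrated mean. An optional logistic tilt links the 3+ probability
  to covariates for testing the assessment-count diagnostics.

Each participant has an independent seeded substream, so output is
byte-reproducible and growing N extends the cohort without reordering it.

What passing tests on this generator do **not** show about real data: real
HRA covariates are correlated within class, symptom scores have item-level
structure the score-level generator ignores, real missingness need not be
MAR, and the published parameters are themselves estimates. The generator
validates the estimation machinery, not the substantive findings.

## Numerical choices and problem sizes

Time bucketing uses a 30.44-day month with lower-exclusive/upper-inclusive
windows; records in the (0, 0.5]-month gap are treated as immediate retakes
and dropped; multiple records in one wave keep the earliest by default
(configurable to latest or mean-before-categorization). A participant needs
two filled waves to enter analysis. Ties in modal assignment break toward
the lower class index; fitted classes are relabeled by decreasing
proportion with ties broken by baseline linear predictor.

Validation experiments are sized to run on one CPU in minutes: the
recovery experiment refits N = 5,000 complete-data participants with 50
starts (proportions recover within 2 percentage points), and the
missingness calibration uses N = 20,000 (mean assessments within 0.05 of
target). Unit and property tests use cohorts of 300–5,000.

## Known limitations

Logit link only; no within-class variance components; no sandwich standard
errors; no LMR/bootstrap likelihood-ratio tests; imputation is PMM-only;
the concomitant-variable refit supports complete covariates only; the
generator produces score-level (not item-level) outcomes and no covariate
drift over time.
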