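# Methods

## The measurement model

Each participant answers 20 sacrificial dilemmas: 10 *incongruent* items in
which the harmful action maximizes overall benefit, each paired with a
*congruent* twin in which the benefit of acting is minimized.  The
processing tree assumes that on any trial the utilitarian
(outcome-maximizing) inclination drives the response with probability U;
otherwise (probability 1 − U) the deontological (harm-rejecting)
inclination drives it with probability D, and with probability
(1 − U)(1 − D) neither does and the harmful action is accepted.  Both
routes reject harm in congruent items, only the deontological route rejects
it in incongruent items, giving

    p(unacceptable | congruent)   = U + (1 − U)·D
    p(unacceptable | incongruent) = (1 − U)·D

Two observed proportions per participant exactly identify the two
parameters, so estimation is algebraic, not iterative:
U = p̂c − p̂i and D = p̂i / (1 − U).  The inverse is exact: the test suite
verifies the round trip to 1e-12 over a dense (D, U) grid.

### Conditioning for regression

Finite-trial proportions make U negative (or D > 1) for some participants.
Following standard practice for probability-valued parameters, negative
estimates are set to 0 (the nearest meaningful value) and estimates are
capped at 1; the conditioned D is computed from the clamped U.  For the
weighted logistic analyses the conditioned values are then rounded to the
nearest multiple of 1/20 (one unit per dilemma), so that weight × value is
an integer success count.  Rounding is nearest-multiple with exact
half-grid ties going away from zero; a 1e-9 epsilon absorbs binary
floating-point slop at the ties.  Clamping precedes rounding.  When U = 1
the incongruent equation carries no information about D, so D is flagged
undefined and the participant is excluded from D analyses explicitly —
never silently zeroed.

## Synthetic cohorts

No raw trial data are available for the studies this package models, so the
generator reproduces their statistical structure:

- **Latent parameters.** Per condition cell, D and U are drawn from
  logit-normal distributions.  The population model for individual
  differences is not identified by published summaries; logit-normal was
  chosen because it respects the [0, 1] support with tunable spread.  The
  (μ, σ) of each cell are calibrated by Gauss–Hermite quadrature and root
  finding so that the population mean and SD equal the published cell
  means and SDs (defaults: the condition-cell tables of the three modeled
  experiments).  σ = 0 degenerates to a point mass.  D and U draws are
  independent by default; a latent correlation knob exists for studying
  condition-dependent parameter correlations.
- **Responses.** Each trial is a Bernoulli draw from the tree probability
  for the participant's (D, U) and the item's congruency.  Item-level
  difficulty heterogeneity is not modeled: passing recovery tests therefore
  shows estimator correctness under the tree model, not robustness to item
  effects.
- **Presentation orders.** Five frozen semi-random orders per condition
  (participants cycle through them), mirroring the study procedure.  Orders
  are uniform over the valid set by rejection sampling of uniform
  permutations; both sequencing constraints (max run of three
  same-congruency items; at least six other items between pair members,
  read as a positional gap of at least seven) are checked globally over the
  full 20-item sequence.  The acceptance rate is about 1.2e-4, so the
  sampler is vectorized (batched integer-key argsort permutations, with the
  rare pair-distance constraint checked first).
- **Processing times.** Per-participant total times are lognormal (default
  median 25 min, σ_log = 0.5 — a realistic session length for 20
  dilemmas); there is no per-trial response-time model because the
  exclusion rule operates on totals.
- **Artifacts.** Duplicate entries replicate a participant's rows verbatim;
  time outliers multiply a participant's total time by
  exp(±12·σ_log), alternating fast/slow.  The ±12 offset guarantees the
  injected values still exceed 3 sample SDs after they themselves inflate
  the sample SD (at injection rates up to ~10%).  Ground-truth labels are
  retained so exclusion tests can demand exact recovery.

## Exclusion rules

Fixed order, logged, idempotent: (1) exact-duplicate removal (first
occurrence kept); (2) participants with |z| > 3 on log total processing
time, with mean and sample SD computed once on the post-deduplication
sample (single pass, not iterative trimming — the modeled analysis reports
a single count of outliers); (3) an optional minimum-total-time compliance
rule, disabled by default because no published threshold exists.  Natural
log is used for "logarithmized" time; the base cancels in z-scores.

## Inference

**Mixed model.** The main analysis is a weighted binomial logit mixed
model: two rows per participant (parameter type D/U as the within-subject
factor), response (successes, failures) = (20·p, 20·(1 − p)), treatment
coding with references D / side-effect / impersonal / female, a random
intercept and a by-participant parameter-type slope with unstructured 2×2
covariance.  The marginal likelihood is maximized under the Laplace
approximation: per-subject modes by damped Newton iterations (step-halving
guarantees monotone ascent of the log-concave subject joint; tolerance
1e-11), outer BFGS on fixed effects plus the Cholesky factor of the
random-effect covariance with three-point finite-difference gradients
(gtol 1e-8), with Nelder–Mead-interleaved restarts because line searches
occasionally stall on finite-difference noise.  Wald covariance is the
inverse Hessian of the Laplace log-likelihood in the fixed effects at the
estimated variance components (central differences).  Fixed effects are
tested both by Wald z and by likelihood-ratio tests against the model
without the term; odds ratios and 95% CIs are exact transforms exp(b),
exp(b ± 1.96·SE).  The implementation is cross-checked in the test suite
against lme4::glmer (itself Laplace) on identical data, and reduces exactly
to the plain weighted logistic regression when the random-effect variance
is pinned to zero.

**Follow-up GLMs.** Separate per-parameter GLMs use statsmodels.  A
Pearson-dispersion check (X²/df on the binomial fit) decides the family;
the flag threshold defaults to 1.5 — no published criterion exists, so the
value is a package decision exposed in configuration.  Under the
quasibinomial family the dispersion is X²/df, standard errors scale by its
square root (coefficients unchanged), and term tests are drop-in-deviance
χ² statistics scaled by the full model's dispersion.  The dispersion is
computed explicitly rather than through statsmodels' `scale="X2"` option,
which mis-scales by the binomial weight for two-column endog.

**Correlations.** Pearson r between the conditioned D and U, overall and
per condition cell, with the usual t test.  Cells are compared with the
Fisher transform, z = (atanh|r₁| − atanh|r₂|)/√(1/(n₁−3) + 1/(n₂−3)),
comparing magnitudes so reported z is sign-free (positive for the stronger
first correlation).  The tail convention is explicit per call and defaults
to two-sided; published analyses of this design mix one- and two-sided
conventions, so the report records which was used.

**Sensitivity analysis.** For the 2 (within) × 2 (between)
repeated-measures interaction, the G*Power convention is the default:
λ = f²·N·m/(1 − ρ), df₁ = (g−1)(m−1), df₂ = (N−g)(m−1), power = upper
tail of noncentral F beyond the central critical value at α.  The minimal
detectable partial η² = f²/(1+f²) is found by bracketed root finding
(inverse-consistent with the forward computation to 1e-6).  An "spss"
convention (λ = f²·N, effect size absorbing m and ρ) is exposed because
published analyses do not always state which was used.  A Monte-Carlo
oracle in the tests exploits that, for m = 2, the interaction F equals the
two-sample t² on within-person difference scores.

## Problem sizes used in the test suite

Simulation-based checks are sized to be decisive yet quick: parameter
recovery uses 1,000 participants per cell (±0.02 tolerance on cell means);
LRT null calibration uses 200 replicates of 40-participant cohorts
(binomial 95% bounds around the nominal 0.05); the Fisher-z null check
uses 2,000 replicate pairs at n = 75; order validation draws 10,000
orders; the Monte-Carlo power oracle uses 10,000 replicates (±0.02).

## Known limitations

- The cohort generator matches cell-level means/SDs, not the full joint
  distribution of real participants; recovered-parameter cell means carry
  a small positive bias from clamping negative U estimates (visible but
  within ±0.02 at 10+10 items).
- The Laplace approximation can understate variance components when the
  number of observations per subject is as small as two; fixed-effect
  estimates and LRTs are the quantities the pipeline reports and they are
  the ones validated against the reference fitter.
- Group-level (pooled-proportion) PD estimation is provided for
  description only; all inferential analyses are individual-level.
- Sequencing constraints are enforced globally over the 20-item sequence;
  no block structure is modeled.
- No maximum-likelihood or Bayesian hierarchical multinomial-processing-
  tree estimation: the 2-parameter design is exactly identified, so the
  closed form suffices.
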