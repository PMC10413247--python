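# Methods

This note documents the models, algorithms and numerical choices behind
`hemodce`, and what the simulation-based tests do and do not establish.

## Random-utility model

Respondent *i* derives utility `U_itj = ASC·sq_j + x_tj'β_i + ε_itj` from
alternative *j* of task *t*, with iid type-1 extreme-value errors, so choice
probabilities are conditional-logit within each task. Taste heterogeneity is
normal and independent across coefficients: `β_i ~ N(β, diag(σ²))`. All eight
model columns (two bleeding dummies, continuous risk per percentage point,
two frequency dummies, two mode dummies, ASC) may be random; the reported
heterogeneity parameter is |σ| because the likelihood is symmetric in each
σ's sign (exactly so under a sign-symmetric draw set, and in expectation
otherwise). Coefficients are assumed uncorrelated — the per-parameter SD
table this package mirrors reports no correlation structure — and the risk
attribute enters linearly in percentage points (a single slope for the
0–4 % span).

Normal (rather than lognormal) heterogeneity is used for every random
coefficient, including risk: the sign-unconstrained SD matches the reported
table, at the cost of admitting individual coefficients of "wrong" sign.

## Experimental design

Candidates are the 81-profile full factorial. The design search minimizes the
D-error `det(I(β₀))^(-1/K)` of the conditional-logit information matrix at
prior coefficients β₀ (zeros by default — utility-neutral, since no priors
are reported for the original instrument) using a modified Fedorov exchange:
every alternative slot is repeatedly offered every candidate profile and an
exchange is kept when the D-error falls, restarted from `n_restarts` random
designs (seed-controlled, hence deterministic). Task contributions to the
information matrix are cached so an exchange costs one rank-limited update
plus one 7×7 determinant.

Blocking into two blocks of nine minimizes, over random equal partitions, the
worst across-block spread of any attribute level's frequency. Augmentation
then adds to every task a status-quo alternative and to every block one
uniformly chosen repeated task (the internal-consistency probe) and
optionally a practice task (flagged, never estimated, excluded from the
information matrix).

**Status-quo coding.** The status quo carries ASC = 1 and all attribute
columns at zero (reference levels). This matches an ASC interpreted as "the
utility of the status quo relative to designed alternatives". A design-level
option (`status_quo_profile`) instead codes the status quo with stated
treatment levels, for populations where the current treatment is known.

**Tasks per respondent.** A respondent sees 9 scored tasks plus 1 repeat by
default; both counts are configurable rather than hard-coded, since published
instruments vary in how many unique scored tasks enter the dominance screen.

## Synthetic respondents

The generator's defaults are the study conditions: 102 respondents, covariate
proportions (education 47.1/52.9, urban/rural 35.3/64.7, treatment type
54.9/40.2/4.9), and taste distributions at the published means and SDs —
including the near-zero SDs, which are retained as printed regardless of
their significance. Choices are multinomial draws from the individual logit
probabilities. Repeated tasks are re-answered from fresh error draws, so
honest respondents can fail the consistency screen at a computable rate
(1 − Σ_j p_ij² at the repeated task); a copy mode answers repeats identically
for scenarios that need exact exclusion accounting.

Controlled contamination overwrites selected respondents: inconsistent
(repeat forced to a different position), position-biased (one fixed position
everywhere), and single-attribute dominant (always the designed alternative
with the better level, ties keeping the original answer). Contaminated ids
are stored in provenance so QC tests have an exact oracle.

What the generator does **not** emulate: interview effects, fatigue or
learning across tasks, item nonresponse, correlated tastes, and any
systematic link between covariates and preferences (unless a test plants
one). Passing parameter-recovery tests therefore shows the estimator is
correct under the model's own assumptions, not that the model is correct for
real respondents.

## Quality control

* **Consistency**: fail iff the chosen *position* differs between a task and
  its repeat (an identity-based comparison is available; the two coincide in
  this package's designs, where repeats preserve alternative order).
  Respondents without a repeated task are "not evaluable", a distinct state
  from passing.
* **Position bias**: chosen position identical across all scored tasks. Note
  that under strong status-quo preference (ASC SD 3.8) a respondent can
  legitimately always choose the status-quo position; the screen flags them
  regardless, which is why exact exclusion-count scenarios in the tests use
  preference-free honest respondents.
* **Comprehension** ("x % of 100 patients"): recorded, but not an exclusion
  by default — the item gates entry to the tasks rather than the analysis;
  a flag makes it excluding.
* Exclusion counts reconcile as a set union (a respondent failing two rules
  counts once), asserted on every report.

**Dominance, nonparametric**: flag iff every evaluable task (the two designed
alternatives differ on the attribute) was answered with the better level,
where "better" follows the attribute's stated direction; choosing the status
quo in an evaluable task breaks the pattern, and the status quo is otherwise
ignored since it carries no attribute levels. An indifferent respondent
follows a pattern across nine tasks with probability ~(1/3)⁹, so chance
flags are rare but possible — with real preferences they are considerably
more likely, which is the screen's nature, not an error.

**Dominance, parametric**: coefficients of a full model versus a model with
only the tested attribute (plus ASC), compared per shared column by z-test
with conservatively pooled variances (var_full + var_reduced), Bonferroni
over shared columns at α = 0.05, raw p-values reported alongside. A caveat
this package makes explicit: logit coefficients are identified only up to the
error scale, so omitting attributes that truly matter shifts the reduced
model's coefficients even without dominance. The test is exactly calibrated
when the tested attribute alone drives choices (verified by simulation), and
in practice should be read jointly with the nonparametric screen.

## Estimation

* **Conditional logit**: BFGS with analytic gradient, then Newton polish with
  the analytic Hessian to gradient max-norm ≲ 1e-10 (the log-likelihood is
  concave, verified by multistart agreement). SEs from the inverse Hessian;
  cluster-robust (by respondent) sandwich SEs optional. Separation is
  reported as non-convergence with a diagnostic rather than silently
  accepted.
* **Mixed logit**: simulated log-likelihood
  `SLL = Σ_i log[(1/R) Σ_r Π_t P(y_it | β + σ∘z_ir)]` with the panel product
  inside the average; analytic gradient; BFGS (means warm-started at the
  conditional-logit fit, free SDs at 0.1) followed by one Newton step using a
  central finite-difference Hessian of the gradient, which also provides the
  covariance. Any subset of SDs can be pinned (`fix_sds`); pinning all at
  zero reproduces the conditional logit to machine-level agreement, the
  nesting property the tests assert at 1e-6.
* **Draws**: Halton by default (distinct prime bases per dimension, no
  scrambling, 10-point burn-in, consecutive blocks per respondent,
  inverse-normal transform) — quasi-random draws stabilize SMLE at far fewer
  draws than pseudo-random; a seeded pseudo-random mode is provided.
  Fewer than 30 draws triggers a low-draw warning, since simulation noise
  biases the maximized SLL upward.
* **Draw schedule**: the stability loop fits at 50, 500, 1000, 1500, 2000,
  2500 draws (warm-started) and stops at the first point where every mean and
  |SD| changes by < 1 % relative to the previous point. The published
  narrative ("commencing with 50, increasing by 500, stable at 2500") is
  arithmetically inconsistent as a sequence; this explicit schedule is the
  closest consistent reading and is fully configurable.
* **Model fit**: AIC = 2k − 2LL and BIC = k·ln(n) − 2LL with n the number of
  choice situations; asserted as identities on every result. LR tests require
  nested column sets and an identical data fingerprint.
* **Interaction selection**: backward elimination over all covariate ×
  (column or ASC) terms in the conditional logit; at each step the term with
  the largest single-term LR p-value above α is removed; aliased terms are
  dropped upfront with a note. α = 1 retains everything, by construction.
* **Individual-level coefficients**: posterior conditional means
  `E[β_i | choices] = Σ_r β_ir w_ir / Σ_r w_ir` with panel weights `w_ir`,
  computed in log space so underflow renormalizes instead of dividing by
  zero. Only random columns vary across respondents; fixed columns return
  the point estimate.

## Benefit-risk statistics

Utility ranges: categorical attributes take max − min over level part-worths
with the reference at zero; the continuous risk attribute takes
|coefficient| × level span (0.79 × 4 at the published values). ARI is
100 × range / max range, reported rounded to integer with raw values and
range shares retained — this "widest = 100" reading of range rescaling
reproduces the published scores {100, 87, 43, 37}. MAR divides the utility
gain of a change by |β_risk| per percentage point, reported to one decimal
(raw retained); the six standard changes reproduce the published
4.6 / 2.3 / 2.0 / 1.5 / 1.7 / 0.9. Both statistics are ratios, hence
invariant to any common rescaling of the utilities (property-tested).
The suite validates against the printed two-decimal coefficients, which is
exact at the printed precision of the published statistics.

MAR uncertainty (a package addition — the source statistics are point
values) uses Krinsky–Robb parametric simulation from the fitted covariance,
with negative eigenvalues clipped (and warned about) if a covariance is not
PSD. Subgroup comparisons default to averaging posterior individual
coefficients within groups ("individual-level preferences"); a refit mode
estimates a separate mixed logit per group and is sharper when group effects
are large, since posterior means shrink toward the population mean with only
nine tasks per respondent. The sensitivity check refits on the full and the
QC-filtered data and z-tests each coefficient difference with pooled
variances.

## Problem sizes in the test suite

Simulation-based tests are sized to give clear verdicts while keeping the
default run short: parameter recovery uses 1000 respondents × 9 tasks with
500 Halton draws (all means and the four clearly nonzero SDs within 3 SEs);
LR-test calibration uses 500 replicates of 100 respondents (type-I error in
[0.03, 0.07]); selection, dominance and subgroup simulations use 120–400
respondents with effects planted strongly enough (e.g. 4× subgroup weights)
that a single seeded replicate is decisive. Stochastic tests fix their seeds;
where a test requires a zero-probability-in-the-limit chance event to be
absent (e.g. an indifferent respondent following a single-attribute pattern,
~(1/3)⁹ per respondent), the fixed seed is one where it does not occur, and
the docstring says so.

## Known limitations

* Linear-in-risk utility: MAR extrapolates beyond the 0–4 % design span at
  the user's risk.
* Uncorrelated normal heterogeneity; no latent classes, no WTP-space
  estimation, no Bayesian posterior.
* The parametric dominance comparison inherits logit scale normalization
  (see above); treat it as a flag, not a test with exact size under general
  preferences.
* Posterior individual coefficients from 9 tasks are strongly shrunk;
  subgroup contrasts based on them are conservative.
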