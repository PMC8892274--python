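# Methods

## The problem

Clinical decision-support alerts in electronic medical record (EMR)
systems are overwhelmingly dismissed, often within a second or two of
appearing — too fast for the alert's content to have been read. One
proposed mechanism is habit: with repeated exposure to the same alert,
dismissal becomes an automatic response triggered by the pop-up itself
rather than a clinical judgment. `alerthabit` operationalises this idea
for timestamped alert event logs: it quantifies each physician's latent
habit strength from their own action history, and tests whether habit
strength predicts subsequent dismissal and faster processing.

## Habit-strength model

Habit strength H is a latent state in [0, 1], one stream per physician,
updated after every alert exposure by a Hebbian / exponentially-weighted
moving-average rule:

    H_{t+1} = H_t + α (a_t − H_t)

where a_t = 1 if the alert was dismissed and 0 if it was acknowledged or
the catheter order was removed, and α ∈ (0, 1) is the learning rate. The
value attached to event k as a predictor is the **pre-action** strength
(accumulated over events 1..k−1 only): including the current action would
leak the outcome into its own predictor. H starts at 0, appropriate for a
newly deployed alert no physician has seen before. Under constant
dismissal the recursion has the closed form H_t = 1 − (1−α)^t, which the
test suite uses as an analytic oracle (agreement to 1e−12 over 1000
steps).

Three learning rates are carried through the whole analysis, α ∈ {0.01,
0.05, 0.1} (columns `H_0.01`, `H_0.05`, `H_0.1`), spanning slow to fast
habit formation; α is fixed, not estimated. The habit stream is per
physician across all of their patients — habitual dismissal is a response
to the alert, not to a particular patient — and is event-indexed: calendar
gaps do not decay it (the days-since-first-alert covariate `day_lag`
carries timing information instead). Ties in timestamp within a physician
are broken lexicographically by alert id so the update has a total order.

## Outcomes and covariates

Per alert instance: `dismiss` (the action was a dismissal) and the nested
automaticity outcomes `dismiss1/2/3`, dismissal in strictly under 1/2/3
seconds ("under K seconds" is read as a strict inequality; a convention
must be fixed for exact tests). Covariates fall into five groups:

* alert context: `ward_round`;
* exposure history: `P_C_total` and `P_C_ward` (cumulative alerts, and
  ward-round alerts, for the physician-patient dyad), `C_total`
  (cumulative alerts for the physician hospital-wide), `C_PatNum`
  (distinct catheterised patients seen by the physician on the current
  calendar day — a day-level count, midnight boundary, not a rolling
  24 h), `day_lag` (whole days since the physician's first alert for the
  patient);
* physician: rank (intern/resident/fellow/attending), specialty,
  department;
* patient: age, gender, race, length of stay, diagnosis count;
* timing: day of week, month.

Cumulative counters include the current event, so each counter's minimum
is 1 rather than 0 on a physician's first alert. Categorical covariates
enter models reference-coded with the modal category as reference, which
is stable under subsampling.

## Regression battery

The central model is a **fixed-effects logistic regression grouped at the
physician level**, estimated by conditional maximum likelihood: the
physician-specific intercept is eliminated by conditioning on each
physician's total number of dismissals, which avoids
incidental-parameter bias when there are hundreds of groups. The
implementation evaluates the conditional likelihood's
elementary-symmetric-function denominator by the standard recursion,
vectorised across groups, with three numerical safeguards: per-group
centring of the linear predictor at its maximum (a group-constant shift
cancels exactly in the conditional likelihood, and it keeps every weight
in (0, 1] so the recursion cannot overflow), the complement identity for
groups whose success count exceeds half their size (recursion depth
min(k, n−k)), and internal column standardisation for optimiser
conditioning (undone exactly on the fitted scale). Gradients are
analytic; the observed information comes from finite differences of the
gradient. Groups without outcome variation carry no conditional
information and are dropped (and counted); covariates constant within
every group (e.g. physician rank) cancel from the likelihood and are
dropped and reported. A unit test checks the estimator against
statsmodels' `ConditionalLogit` on a subset (agreement ~1e−4); the
in-package implementation exists because the validation battery needs
hundreds of fits and the recursion here is roughly an order of magnitude
faster.

Robustness estimators: a plain (pooled) logistic fit, and a
**random-intercept logistic** fit by maximum likelihood with the
physician intercept u_g ~ N(0, σ_u²) integrated out by Gauss–Hermite
quadrature (25 nodes; the per-group marginal likelihood is verified
against adaptive quadrature to 1e−8 in tests). From σ_u² the
latent-threshold intraclass correlation is

    ICC = σ_u² / (σ_u² + π²/3)

the share of unexplained latent-scale variance attributable to the
physician level (π²/3 is the logistic residual variance). Effect sizes
are reported as odds ratios exp(β), and per-SD effects as exp(β·s) with
exp(β·s) − 1 the relative "increase in odds" for a one-SD increase in
habit strength.

Processing time is modelled linearly (optionally on the log scale) with
fixed-effects (within transformation, degrees of freedom n − p − G),
random-effects (REML via statsmodels `MixedLM`) and pooled OLS
estimators. Rank-stratified fits run the fixed-effects model separately
per physician rank; strata that cannot be estimated produce a failure
record rather than an exception.

Convergence: BFGS/L-BFGS-B with tolerance 1e−8 and a 200-iteration cap;
non-convergence is flagged on the result, never silently ignored.

## Synthetic-data generator

The generator draws physicians (rank, specialty, department, random
intercept u_j ~ N(0, σ_u²)) and patients (age, gender, race, length of
stay, diagnosis count), assigns physician-patient dyads with
negative-binomial alert counts, and iterates each physician's alerts in
time order maintaining H with learning rate `alpha_true`. Each alert is
dismissed with probability logistic(β₀ + β_H·H_pre + γ'x + u_j), the
**realised** action updates H (the self-reinforcing loop that motivates
the analysis), and processing time is lognormal with log-mean
θ₀ − θ₁·H_pre. Identical seeds give byte-identical CSV output, and
feeding the realised dismissals back through the update rule reproduces
the generator's latent H exactly (tested to 1e−12).

Defaults describe a large hospital deployment of a catheter-reminder
alert: 200 physicians, 400 patients, ~7 dyads per physician and ~8 alerts
per dyad (negative-binomial dispersion 0.5, so SD ≈ 12), giving ~57
alerts per physician; ward-round probability 0.456; age ~ N(68, 16)
truncated to [16, 105]; right-skewed length of stay with mean ≈ 38 days;
β₀ = 1.5 so that with β_H = 1 and σ_u = 1 roughly 90% of alerts are
dismissed; θ₀ = 1.65, θ₁ = 0.9, σ_e = 0.5 so mean processing time falls
from about 5.9 s at first exposure toward about 2.4 s by the 60th. The
acknowledge/remove_order split among non-dismissals is 50/50; both code
a = 0, so the split affects no implemented statistic. The alerts-per-dyad
distribution shape (negative binomial) is a modelling choice constrained
only by its mean/SD/maximum.

What the generator does **not** emulate: real specialty/department
case-mix, alert bursts within a chart-open session, physician turnover,
secular trends, or any dependence of covariates on past outcomes. Passing
recovery tests therefore show that the estimators recover the assumed
generative structure, not that the structure is true of any hospital.

### A note on the count fixture

The exact-count fixture (`fixture_from_counts`) realises given marginal
counts — total alerts, dismissals, and dismissals under 1/2/3 s — with
synthesised ids and constant clinical covariates. It exists to verify the
descriptive layer against reference count-derived percentages; it
carries no covariate structure, and the pipeline skips the regression
stages on such input. One arithmetic note: from the counts 8,750/66,049
and 37,546/66,049 the percentages are 13.2% and 56.8% at one decimal;
roundings of 13.3% and 56.9% sometimes quoted for these two shares do
not match their own counts, and the count-derived values are treated as
authoritative throughout.

## Validation studies and a known estimator limitation

`alerthabit.validation` runs end-to-end recovery studies: simulate,
rebuild features, fit, compare to ground truth. The fits control for the
covariates the generator actually uses (ward round, age, length of stay;
rank is group-constant and absorbed).

Two findings matter for interpretation:

* **The conditional fixed-effects estimator is attenuated under the
  self-reinforcing loop.** H_pre is predetermined — a deterministic
  function of the physician's past outcomes — so strict exogeneity
  fails, and conditioning on the group's success total induces a
  mechanical negative dependence between accumulated habit and the
  remaining outcomes (given the total, a high running success count
  implies fewer successes left). At the default conditions (β_H = 1)
  the mean conditional-ML estimate is ≈ 0.77–0.82, the bias does not
  vanish with longer series, and with β_H = 0 the nominal-5% Wald test
  over-rejects substantially. With an exogenously driven habit stream
  the same estimator is unbiased with nominal coverage, and it agrees
  with statsmodels on fixed designs — the attenuation is a property of
  the design, not the optimiser. Sign and order-of-magnitude inference
  are unaffected.
* **The random-intercept ML estimator remains consistent under the
  loop**, because its likelihood factorises sequentially over events
  (each term conditions only on the past); it recovers β_H ≈ 1.0 and a
  true latent ICC of 0.5 to within ±0.05–0.1 at 300 physicians. When
  the two estimators disagree systematically on feedback-generated
  data, that is expected, and the random-effects estimate is the less
  biased one for the habit coefficient.

The latency study recovers the negative habit-processing-time
association essentially always (CI excluding zero in ~100% of
replicates at θ₁ = 0.9), and a null latency generator (θ₁ = 0) yields
CIs covering zero at the nominal rate.

One further structural caveat: with σ_u > 0 the marginal correlation
between dismissal and habit strength is positive even when β_H = 0,
because dismissal-prone physicians accumulate high H from their own
past actions. Between-physician confounding of this kind is exactly what
the grouped estimators are there to remove; raw correlations overstate
the within-physician effect.

## Problem sizes

The validation battery uses 100 recovery replicates and 200 null
replicates at the default 200-physician size, one 300-physician dataset
for ICC recovery, and 100 replicates for the latency sign study. The
acceptance script reports the same quantities from 30–40 replicates,
chosen as a compact summary of the same studies.

## Known limitations

* α is fixed, never estimated; no habit transfer across alert types.
* No decay of habit over calendar time.
* Conditional-ML attenuation under self-reinforcement (above): FE-logit
  coefficients on feedback-generated or real habitual data should be
  read as conservative in magnitude.
* Standard errors are model-based; no clustering beyond the grouping.
* The descriptive layer reproduces count-derived percentages exactly but
  makes no attempt to reproduce statistics computable only from raw
  hospital data.
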