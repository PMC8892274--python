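# alerthabit

Habit-strength modelling and regression analysis of EMR alert-dismissal
event logs.

Clinical decision-support alerts are dismissed at very high rates, often
within a second or two of appearing — a signature of automatic, habitual
responding rather than clinical judgment. `alerthabit` is for health
informatics researchers and hospital analytics teams who have a
timestamped alert event log (one row per alert instance: physician,
patient, timestamp, action, processing time, clinical context) and want
to quantify habitual dismissal and its association with subsequent
behaviour.

## The model

Each physician carries a latent habit strength H ∈ [0, 1], updated after
every alert exposure by a Hebbian / EWMA learning rule

> H_{t+1} = H_t + α (a_t − H_t)

with a_t = 1 if the alert was dismissed (0 otherwise) and learning rate
α ∈ (0, 1); three rates α ∈ {0.01, 0.05, 0.1} are carried through the
analysis. The **pre-action** strength (habit accumulated before the
current alert) then enters a battery of grouped regressions:

* conditional (fixed-effects) logistic regression of dismissal — and of
  dismissal in under 1/2/3 seconds — grouped at the physician level;
* random-intercept logistic regression, with the latent-threshold
  intraclass correlation ICC = σ_u² / (σ_u² + π²/3);
* linear fixed/random-effects and pooled models of alert processing
  time.

Alongside the models: event-log I/O and validation, outcome and
covariate construction (dyad exposure counters, calendar effects),
descriptive summaries, point-biserial/Pearson correlation matrices, and
a synthetic event-log generator with known ground truth for end-to-end
validation. See `docs/methods.md` for the full model description,
estimator details and known limitations.

## Worked example

Simulate a 60-physician log, build the analysis table, and fit the main
model (every step also works on your own CSV export; see the column
schema in `alerthabit/event_log.py` and the `--column-map` option):

```sh
$ alerthabit simulate --config sim.yaml --seed 7 --out log.csv
wrote 3890 events to log.csv
$ alerthabit features log.csv --out table.csv
wrote 3890 analysis rows to table.csv
$ alerthabit describe table.csv --out-dir desc
pct_dismissed: 85.7%
pct_under1_of_all: 2.1%
...
$ alerthabit fit table.csv --covariates "ward_round,patient_age,length_of_stay" --out model.json
H_0.05: coef=1.0298 se=0.2182 CI [0.6021, 1.4575]
$ alerthabit fit table.csv --processing-time \
    --covariates "ward_round,patient_age,length_of_stay" --out pt.json
H_0.05: coef=-3.3051 se=0.1319 CI [-3.5637, -3.0466]
```

The generator's true habit effect here is β_H = 1.0 on the log-odds
scale: the fitted conditional-ML coefficient 1.03 (95% CI 0.60–1.46)
recovers it, i.e. moving from no habit (H = 0) to full habit (H = 1)
multiplies the within-physician odds of dismissal by exp(1.03) ≈ 2.8.
The processing-time model recovers the negative habit-latency
association: a fully habituated physician responds about 3.3 seconds
faster on this dataset. `alerthabit run-all --simulate --seed 7
--out-dir bundle` produces the whole report bundle (analysis table,
summary statistics, correlation matrices, the 12-model grid of 3 habit
measures × 4 outcomes, processing-time models, and a hashed manifest)
in one command.

As a library, the same steps are `simulate_log` / `read_event_log` →
`assemble_analysis_table` → `summarize_log` / `correlation_matrix` /
`fit_fe_logit`; the transformers (`HabitStrengthTransformer`,
`AnalysisTableBuilder`) and estimators (`ConditionalLogisticRegression`,
`RandomInterceptLogisticRegression`, `WithinGroupOLS`) follow
scikit-learn conventions (`get_params`, `fit(X, y, groups)`, fitted
attributes with trailing underscores).

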