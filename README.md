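# interopipe

Multidimensional cardiac and gastric interoception analysis for
psychophysiology research: physiological and behavioral feature extraction,
POMP-based interoceptive-insight scoring, and a cross-validated comparison
of multiple linear regression against the LASSO for explaining emotional,
external and restrained eating styles.

The package is aimed at researchers who run interoception protocols —
heartbeat counting, resting ECG/EGG, the two-step water load test, the
Dutch Eating Behaviour Questionnaire (DEBQ) — and want a tested, fully
reproducible path from raw instrument data to the final model comparison.
Because real lab data is rarely shareable, every stage can also be
exercised on a built-in synthetic cohort generator with recorded ground
truth.

## What it computes

**Cardiac domain.** Heartbeat-counting accuracy per session,

> score = mean over trials of max(0, 1 − |actual − reported| / actual),

mean confidence (0–8 Likert), mean HR, RMSSD, and HFnu =
100·HF/(LF + HF) from a Welch spectrum of the artifact-corrected,
4-Hz-resampled inter-beat series (LF 0.04–0.15 Hz, HF 0.15–0.40 Hz).

**Gastric domain.** EGG band powers from 240-s runs with 75 % overlap
(Hann taper, zero-padding to the next power of two) integrated over
bradygastria 1–2.5 cpm, normogastria 2.5–3.75 cpm and tachygastria
3.75–10 cpm, as percentages of total 1–15 cpm power; water-load volumes
(satiation, additional, total, % satiation of maximum fullness) and
questionnaire scores including a five-item negative-affect scale with
Cronbach's alpha.

**Insight scoring.** Objective and self-report measures are mapped to a
common 0–100 scale with the Percent-Of-Maximum-Possible transform,
POMP(x) = (x − min)/(max − min)·100, and interoceptive insight is
100 − |POMP(self-report) − POMP(objective)| — defined even when confidence
has zero variance, unlike a within-person correlation.

**Statistics.** Spearman correlation matrices, VIF-based multicollinearity
screening (threshold 10, one variable of interest retained per
interoceptive dimension), and — on standardized data — OLS with classical
inference next to a 10-fold cross-validated LASSO, compared by out-of-fold
R², RMSE and MAE on shared folds. A power module computes a-priori sample
sizes for the omnibus F-test via the noncentral F distribution
(noncentrality f²·N): with 12 predictors, f² = 0.15, α = 0.05 and target
power 0.80 the required sample is N = 127.

## Worked example

Insight for a participant with mean counting accuracy 0.25 but mean
confidence 6.5:

```python
from interopipe import pomp, insight_score
acc, conf = pomp(0.25, 0, 1), pomp(6.5, 0, 8)
print(acc.value, conf.value, insight_score(acc, conf).value)
# 25.0 81.25 43.75
```

Even though such a participant's trial-level accuracy and confidence can
correlate perfectly, the absolute-difference score shows only 43.75/100
insight — the miscalibration a correlation hides.

Full pipeline on a synthetic cohort:

```python
from interopipe import CohortConfig, InteroceptionModel, simulate_cohort

cohort = simulate_cohort(CohortConfig(n_participants=128, seed=1))
res = InteroceptionModel(cohort.features, "debq_emotional").fit(folds=10, seed=1)
print(res.summary())
```

```
Outcome: debq_emotional   n = 128
OLS: R² = 0.262, F(13, 114) = 3.11, p = 0.001
LASSO: lambda = 0.04971, 8/13 nonzero coefficients

                        beta  std_error  t_value  p_value  lasso_beta
normo_pct            -0.3079     0.0869  -3.5422   0.0006     -0.2424
negative_affect_t2    0.2290     0.0857   2.6715   0.0087      0.1664
hbct_accuracy        -0.4350     0.2018  -2.1558   0.0332     -0.1376
...

Cross-validated prediction (shared folds):
       r_squared    rmse     mae
ols       0.1674  0.9751  0.7801
lasso     0.1834  0.9549  0.7572
```

The coefficient table lists standardized OLS betas with their standard
errors, t and p values beside the LASSO coefficients at the
cross-validation-selected penalty (zeros mean the predictor was dropped);
here the LASSO keeps 8 of 13 columns and beats OLS out of fold on RMSE and
MAE. The generator planted its largest weights on the negative-affect and
normogastria columns, which is exactly what both models recover.

A command-line interface covers the same flow on CSV inputs
(`interopipe simulate|features|score|analyze|report`); signals travel as
CSV sample files with a JSON sidecar declaring `sample_rate_hz`.

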