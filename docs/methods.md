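# Methods

This note documents the models, conventions and default parameters behind
interopipe, the reasoning for choices the instruments themselves do not
dictate, and what validation on synthetic data does and does not show.

## Cardiac pipeline

**Beat detection.** `detect_rpeaks` band-passes the ECG to the QRS range
(5–30 Hz), squares the derivative, smooths over 120 ms, and thresholds at
30 % of the 99th envelope percentile with a 250 ms refractory period. The
threshold is relative, so detection is invariant to amplitude scaling.
This detector is intended for clean laboratory ECG; it makes no attempt at
morphology classification.

**Artifact correction.** An interval deviating more than 25 % from the
median of its 11-interval neighbourhood is replaced by linear interpolation
between the nearest clean neighbours. If more than 20 % of intervals are
flagged the recording is rejected outright rather than repaired. Both
numbers are conventional quality-control settings, exposed as arguments.

**Heartbeat counting.** Per-trial accuracy is 1 − |actual − reported| /
actual. A trial where the participant reports more than twice the actual
count would go negative; we clip at zero so the session score stays within
its documented 0–1 range. Confidence is the plain mean of the four 0–8
ratings.

**HRV.** RMSSD and mean HR come straight from the corrected intervals
(mean HR from the mean interval, which is the stable convention). For the
frequency domain, the irregular RR series is resampled to an even 4 Hz grid
by a cubic spline over cumulative beat times, mean-centred, and analysed
with a Welch averaged periodogram (Hann window, 128-s segments). LF is
0.04–0.15 Hz and HF 0.15–0.40 Hz (the standard task-force bands), and
HFnu = 100·HF/(LF + HF). Whether to window/detrend the RR series before the
FFT is genuinely open in many published descriptions; the Welch convention
here is a documented, reproducible choice, and the synthetic oracles (pure
LF or HF modulation → HFnu near 0 or 100; balanced modulation → 50 ± 3)
pin its behaviour.

## Gastric pipeline

**EGG.** Preprocessing: zero-phase Butterworth band-pass 0.016–0.25 Hz
(1–15 cpm) at the native rate, linear interpolation of flagged gaps,
resampling to 10 Hz, mean removal. The 0.25 Hz low-pass sits far below the
5 Hz Nyquist of the target rate, so the filter itself is the anti-alias
guard. Spectra are estimated on 240-s runs stepping 60 s (75 % overlap);
each run is Hann-tapered and zero-padded from 2400 to 4096 samples, and the
per-run periodograms are averaged (a Welch estimator — the combination rule
when runs and overlap are specified but the estimator is not).

Band percentages use the **total 1–15 cpm power as denominator**, not the
sum of the three bands: published cohort band means of roughly 41 + 35 + 20
do not reach 100, implying an unassigned 10–15 cpm remainder, and this
convention reproduces that property (brady + normo + tachy ≤ 100). Band
edges are half-open [low, high) cpm so 2.5 cpm belongs to normogastria —
an explicit tie-break rather than a floating-point accident.

**Water load.** The volume indices are pure arithmetic (total = satiation +
additional; percentage of satiation = 100·satiation/total). Questionnaire
scoring passes satiation and fullness through and averages the five
negative-affect items; the analysis timepoint defaults to t2
(post-ingestion). Cronbach's alpha uses sample variances with the n−1
denominator.

## Insight scoring

POMP bounds are the **theoretical instrument bounds** (accuracy 0–1,
confidence 0–8, satiation rating 1–7, percentages 0–100), not sample
min/max: sample-based bounds would make one participant's insight depend on
who else was in the cohort. Gastric insight pairs the satiation percentage
with the satiation rating taken at t1 — the end of the drinking phase the
satiation volume refers to; the timepoint is configurable because protocols
differ. DEBQ subscale means are computed when at least 8 of 10 items are
present, otherwise treated as missing.

## Screening and regression

VIF screening regresses each predictor on all the others (VIF = 1/(1−R²),
threshold 10). Exactly collinear columns are flagged as aliased. When any
member of a dimension group (the WLT volume indices; the EGG bands) exceeds
the threshold, the whole group collapses onto its designated variable of
interest (the satiation percentage; normogastria) — dropping offenders one
at a time would let the remaining group members fall back under the
threshold and survive, which is not how "one variable per dimension" is
meant to resolve.

All regressions run on standardized data (mean 0, sd 1, n−1 denominator),
**outcome included**, so OLS and LASSO coefficients are standardized betas
on one scale. The binary sex covariate is standardized and penalized like
any other column; leaving it unpenalized would prevent the near-zero LASSO
sex coefficients that shrinkage produces in practice.

The LASSO objective is (1/2n)·‖y − Xβ‖² + λ‖β‖₁ (coordinate descent,
tolerance 1e−7), so λ_max = max_j |⟨x_j, y⟩|/n zeroes every coefficient.
The penalty grid is 100 geometric points over three decades down from
λ_max; λ is chosen to minimise mean out-of-fold RMSE (not the 1-SE rule,
which optimises parsimony rather than predictive error). Cross-validated
R² is the mean over folds of the squared prediction–observation
correlation, while RMSE/MAE pool all out-of-fold residuals; the two can
rank models differently, which is a property of the metrics, not a bug.
`repeats` > 1 averages over repeated 10-fold splits for users who read
"10 repetitions" as repeated cross-validation rather than the rotation over
10 folds (the default).

Power for the omnibus F-test uses the noncentral F distribution with
noncentrality f²·N. The effect-size argument follows the **f² convention**:
an input of 0.15 with 12 predictors, α = 0.05 and target power 0.80 yields
N = 127, whereas reading 0.15 as Cohen's f (f² = 0.0225) would demand a
several-fold larger sample. At f² → 0 the power correctly collapses to α.

## Synthetic cohort generator

The generator emulates the full study design with n = 128 participants by
default and records everything the pipeline must recover.

* **IBI series**: interval_k = mean + A_LF·sin(2πf_LF t) + A_HF·sin(2πf_HF t)
  + noise; defaults mean 890 ms (≈ 67 bpm) with 140 ms between-participant
  sd, A_LF = 35 ms, A_HF = 40 ms at 0.10/0.25 Hz, white noise 10 ms, and
  log-normal per-participant amplitude scalings (sd 0.35). Sinusoidal
  amplitude modulation was chosen over an integrate-and-fire pulse model
  because it gives closed-form control of RMSSD and the HF/LF balance.
* **EGG**: sinusoids at the band midpoints 1.75/3.125/6.875 cpm (midpoints
  maximise distance from band edges, minimising leakage ambiguity) with
  squared-amplitude proportions drawn per participant from a Dirichlet
  around (0.40, 0.36, 0.18), plus 6 % 1/f noise; 15 min at 50 Hz.
* **HBCT**: reported = round(gain·actual + noise) floored at 0; population
  gain 0.60 ± 0.25 (clipped to [0, 1.5]), report noise sd 2 counts;
  confidence = clamp(round(1.5 + 4·gain + noise), 0, 8).
* **WLT**: log-normal volumes (medians ≈ 410/320 ml, matching typical
  satiation/additional volumes near 450/370 ml with their observed
  skew); a monotone map from the satiation percentage to the 1–7 rating
  scale (offset 1, slope 0.06/pct, noise sd 1.2); five negative-affect
  items from one latent factor (unit loadings, item noise 1.1), which puts
  scale reliability near the α ≈ 0.8 typical of this instrument.
* **Outcomes**: DEBQ scores are generated at subscale level from a sparse
  linear model over the standardized extracted features — dominant weight
  on negative affect for all three eating styles, with outcome-specific
  secondary weights — plus Gaussian noise (sd 0.9), then mapped affinely
  into the 1–5 DEBQ range. Item-level DEBQ generation is out of scope
  because the analysis consumes subscale means only.
* **Missingness** is completely at random per instrument, with an optional
  dropout process that removes all laboratory instruments at once
  (questionnaires survive). `STUDY_MISSING_RATES` mirrors per-instrument
  missing counts of the order observed in comparable lab studies. MCAR is a
  deliberate simplification: recording losses from technical issues are not
  outcome-dependent.

No measured variable's distributional family is dictated by the
instruments; the log-normal/Gaussian choices above are conventions, stated
once and frozen.

**What synthetic validation shows — and does not.** Passing tests show the
pipeline recovers known spectral compositions, perception gains and
regression coefficients from data generated under its own assumptions
(stationary sinusoidal physiology, MCAR missingness, linear outcome
models). They do not certify behaviour on real recordings with
non-stationary rhythms, movement artifacts, electrode drift or informative
missingness — the quality-control hooks exist for those, but their
thresholds substitute for, and cannot replicate, visual inspection.

## Determinism and problem sizes

Every stochastic step takes an explicit seed and a single generator drives
cohort assembly, so identical (config, seed) yields bit-identical cohorts
and byte-identical analysis reports. The validation suite runs cohorts of
60–128 participants, 50-replicate LASSO support-recovery simulations at
n = 500, and null simulations at n = 10⁴ — sizes chosen so each oracle's
Monte-Carlo error is well below its assertion tolerance while the full
suite stays fast enough to run on every change.

## Known limitations

* No nonlinear HRV indices, respiration correction or very-low-frequency
  analysis; single-channel EGG only, no running-spectrum instability
  metrics.
* The R-peak detector expects laboratory-quality ECG and a simple template
  morphology.
* Insight is the absolute-difference POMP score only; within-person
  confidence–accuracy correlations are not offered as an estimator (they
  are undefined under zero confidence variance), though the confidence
  variance is visible in the session data for diagnostic use.
* Inference after LASSO selection (selective inference) is out of scope;
  the LASSO column is descriptive, the classical inference belongs to OLS.
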