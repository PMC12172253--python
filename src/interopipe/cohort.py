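"""Synthetic study-cohort generator with recorded ground truth.

Every instrument of the study design is emulated so the full pipeline —
feature extraction, insight scoring, multicollinearity screening and the
OLS/LASSO comparison — can be exercised and validated without any external
data:

* inter-beat-interval (IBI) series with sinusoidal LF/HF amplitude
  modulation of interval length, giving closed-form control over RMSSD and
  the HF/LF power balance;
* EGG traces built from sinusoids at the gastric band centres (bradygastria
  1.75 cpm, normogastria 3.125 cpm, tachygastria 6.875 cpm) whose
  squared-amplitude proportions equal the requested band fractions, plus
  1/f background noise;
* heartbeat-counting sessions under a perception-gain model
  (reported = round(gain x actual + noise), floored at 0);
* two-phase water-load records with log-normal volumes, a monotone
  volume-to-rating map and a one-factor negative-affect item model;
* DEBQ outcomes generated from a known sparse linear model over the
  standardized extracted features, then affinely mapped into the 1-5 DEBQ
  range;
* per-instrument missing-completely-at-random masking, with an optional
  dropout process that removes all laboratory instruments at once.

Defaults are chosen to land the cohort near the descriptive statistics of a
resting adult sample (HR about 68 bpm, RMSSD about 40 ms, satiation volume
about 450 ml, normogastric share about 35 %).  The same config and seed
always yield a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import stats as ip_stats
from .cardiac import BeatSeries, HBCTSession, HBCTTrial, HBCT_TRIAL_DURATIONS
from .exceptions import InsufficientDataError, InvalidParameterError
from .features import INSTRUMENT_FEATURES, participant_features
from .gastric import EGGRecording, TimepointRatings, WLTRecord, NA_ITEMS
from .scoring import COVARIATE, OUTCOMES, PREDICTORS

#: cpm centres of the synthetic EGG band components (band midpoints).
BAND_CENTER_CPM = {"brady": 1.75, "normo": 3.125, "tachy": 6.875}

LAB_INSTRUMENTS = ("hbct", "ecg", "egg", "wlt")

__all__ = [
    "IBIParams",
    "EGGParams",
    "HBCTParams",
    "WLTParams",
    "OutcomeParams",
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "simulate_ibi_series",
    "simulate_egg_signal",
    "simulate_hbct_session",
    "simulate_wlt_record",
    "simulate_outcomes",
    "apply_missingness",
    "simulate_cohort",
    "default_betas",
    "BAND_CENTER_CPM",
]


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class IBIParams:
    """Sinusoidal amplitude-modulation model of the inter-beat series (ms)."""

    mean_ibi: float = 890.0
    mean_ibi_sd: float = 140.0  # between-participant spread, cohort level
    lf_amplitude: float = 35.0
    hf_amplitude: float = 40.0
    lf_freq: float = 0.10  # Hz
    hf_freq: float = 0.25  # Hz
    noise_sd: float = 10.0

    def __post_init__(self):
        if self.mean_ibi <= 0:
            raise InvalidParameterError("mean_ibi must be positive")
        if self.lf_amplitude < 0 or self.hf_amplitude < 0 or self.noise_sd < 0:
            raise InvalidParameterError("amplitudes and noise_sd must be >= 0")
        if self.mean_ibi_sd < 0:
            raise InvalidParameterError("mean_ibi_sd must be >= 0")


@dataclass
class EGGParams:
    """Band composition of the synthetic gastric signal.

    ``band_fractions`` are the squared-amplitude proportions of the brady,
    normo and tachy sinusoids; the remainder up to 1 plus ``noise_fraction``
    of total variance is 1/f background noise.
    """

    band_fractions: tuple = (0.40, 0.36, 0.18)
    noise_fraction: float = 0.06
    duration_s: float = 900.0
    sample_rate: float = 50.0

    def __post_init__(self):
        bf = np.asarray(self.band_fractions, dtype=float)
        if bf.size != 3 or np.any(bf < 0):
            raise InvalidParameterError("band_fractions must be 3 non-negative values")
        if bf.sum() > 1 + 1e-9:
            raise InvalidParameterError("band_fractions must sum to <= 1")
        if not 0 <= self.noise_fraction:
            raise InvalidParameterError("noise_fraction must be >= 0")
        if self.sample_rate < 2:
            raise InvalidParameterError("sample_rate must be >= 2 Hz")
        if self.duration_s < 480:
            raise InvalidParameterError(
                "duration must cover two 240-s analysis runs (>= 480 s)"
            )


@dataclass
class HBCTParams:
    """Perception-gain model of heartbeat counting.

    A participant's reported count is ``round(gain x actual + noise)``
    floored at 0; confidence follows a linear-in-gain model clamped to the
    0-8 Likert range.  ``perception_gain`` is the population mean,
    ``gain_sd`` the between-participant spread (draws clipped to [0, 1.5]).
    """

    perception_gain: float = 0.60
    gain_sd: float = 0.25
    report_noise_sd: float = 2.0
    confidence_intercept: float = 1.5
    confidence_slope: float = 4.0
    confidence_noise_sd: float = 2.0

    def __post_init__(self):
        if not 0 <= self.perception_gain <= 1.5:
            raise InvalidParameterError("perception_gain must lie in [0, 1.5]")
        if self.gain_sd < 0 or self.report_noise_sd < 0 or self.confidence_noise_sd < 0:
            raise InvalidParameterError("noise parameters must be >= 0")


@dataclass
class WLTParams:
    """Water-load volumes and questionnaire model.

    Volumes are log-normal; ratings are produced by a monotone map from the
    satiation percentage onto the 1-7 scale (``rating = round(offset +
    slope x pct + noise)`` clamped); the five negative-affect items load on
    one latent factor, so scale reliability is tunable through the loadings
    and the item noise.
    """

    log_satiation_mean: float = 6.02  # exp -> ~450 ml
    log_satiation_sd: float = 0.45
    log_additional_mean: float = 5.76  # exp -> ~365 ml
    log_additional_sd: float = 0.54
    rating_slope: float = 0.06  # rating points per pct point
    rating_offset: float = 1.0
    rating_noise_sd: float = 1.2
    na_loadings: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)
    na_noise_sd: float = 1.1
    na_mean_t2: float = 2.9

    def __post_init__(self):
        if self.rating_slope <= 0:
            raise InvalidParameterError("rating map must be monotone increasing")
        if len(self.na_loadings) != len(NA_ITEMS):
            raise InvalidParameterError(f"need {len(NA_ITEMS)} NA loadings")
        if self.na_noise_sd < 0 or self.rating_noise_sd < 0:
            raise InvalidParameterError("noise parameters must be >= 0")


def default_betas() -> pd.DataFrame:
    """Sparse true coefficient matrix (predictors + sex) x outcomes.

    The nonzero pattern places the dominant weight on the negative-affect
    scale for all three eating styles, with secondary cardiac/gastric
    weights differing by outcome.
    """
    rows = PREDICTORS + [COVARIATE]
    betas = pd.DataFrame(0.0, index=rows, columns=OUTCOMES)
    betas.loc["negative_affect_t2"] = [0.20, 0.30, 0.25]
    betas.loc["fullness_t2", "debq_emotional"] = 0.21
    betas.loc["normo_pct", "debq_emotional"] = -0.15
    betas.loc["cardiac_insight", "debq_emotional"] = 0.11
    betas.loc["hfnu", "debq_emotional"] = -0.10
    betas.loc["mean_hr", "debq_emotional"] = -0.10
    betas.loc["hbct_accuracy", "debq_emotional"] = -0.10
    betas.loc["sex", "debq_restrained"] = -0.20
    betas.loc["mean_hr", "debq_restrained"] = -0.15
    betas.loc["rmssd", "debq_restrained"] = 0.10
    return betas


@dataclass
class OutcomeParams:
    """Linear outcome model: standardized features x betas + noise."""

    betas: pd.DataFrame = field(default_factory=default_betas)
    residual_sd: float = 0.9

    def __post_init__(self):
        if self.residual_sd < 0:
            raise InvalidParameterError("residual_sd must be >= 0")


#: Missing-data rates shaped like the study's per-instrument missing counts.
STUDY_MISSING_RATES = {
    "dropout": 0.07,
    "hbct": 0.05,
    "wlt": 0.084,
    "ecg": 0.025,
    "egg": 0.084,
    "debq": 0.0625,
}


@dataclass
class CohortConfig:
    n_participants: int = 128
    seed: int = 0
    ibi_params: IBIParams = field(default_factory=IBIParams)
    egg_params: EGGParams = field(default_factory=EGGParams)
    hbct_params: HBCTParams = field(default_factory=HBCTParams)
    wlt_params: WLTParams = field(default_factory=WLTParams)
    outcome_params: OutcomeParams = field(default_factory=OutcomeParams)
    missing_rates: dict = field(default_factory=dict)
    male_fraction: float = 0.094
    resting_ecg_duration_s: float = 300.0
    task_ecg_duration_s: float = 200.0

    def __post_init__(self):
        if self.n_participants < 1:
            raise InvalidParameterError("n_participants must be >= 1")
        for k, v in self.missing_rates.items():
            if k not in LAB_INSTRUMENTS + ("debq", "dropout"):
                raise InvalidParameterError(f"unknown instrument {k!r}")
            if not 0 <= v < 1:
                raise InvalidParameterError(f"missing rate for {k!r} must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    per_participant: pd.DataFrame  # gains, band fractions, amplitudes, latents
    betas: pd.DataFrame
    residual_sd: float
    features_complete: pd.DataFrame  # extracted features before masking


@dataclass
class SyntheticCohort:
    config: CohortConfig
    participants: pd.DataFrame  # id, sex, weight, height + debq outcomes
    beat_series: dict  # id -> BeatSeries or None (resting ECG)
    hbct_sessions: dict  # id -> HBCTSession or None
    wlt_records: dict  # id -> WLTRecord or None
    egg_recordings: dict  # id -> EGGRecording or None
    features: pd.DataFrame  # per-participant features with NaN for missing
    ground_truth: GroundTruth
    missing_log: pd.DataFrame = None


def simulate_ibi_series(ibi_params: IBIParams, duration_s: float, seed=0) -> BeatSeries:
    """Inter-beat series with sinusoidal LF/HF modulation of interval length.

    interval_k = mean + A_lf sin(2 pi f_lf t_k) + A_hf sin(2 pi f_hf t_k)
    + Gaussian noise, generated until cumulative time reaches ``duration_s``.
    """
    p = ibi_params
    if duration_s <= 10 * p.mean_ibi / 1000.0:
        raise InvalidParameterError("duration must exceed 10 mean beats")
    rng = _rng(seed)
    phase_lf = rng.uniform(0, 2 * np.pi)
    phase_hf = rng.uniform(0, 2 * np.pi)
    intervals = []
    t = 0.0
    while t < duration_s:
        iv = (
            p.mean_ibi
            + p.lf_amplitude * np.sin(2 * np.pi * p.lf_freq * t + phase_lf)
            + p.hf_amplitude * np.sin(2 * np.pi * p.hf_freq * t + phase_hf)
        )
        if p.noise_sd > 0:
            iv += rng.normal(0, p.noise_sd)
        iv = max(iv, 0.2 * p.mean_ibi)  # physiological floor
        intervals.append(iv)
        t += iv / 1000.0
    return BeatSeries(np.array(intervals), origin="simulated")


def simulate_egg_signal(egg_params: EGGParams, seed=0) -> EGGRecording:
    """Sum of band-centre sinusoids plus 1/f noise.

    Sinusoid squared amplitudes are proportional to ``band_fractions`` and
    the 1/f noise variance to ``noise_fraction`` (out of a total variance
    budget of band fractions + noise fraction).
    """
    p = egg_params
    rng = _rng(seed)
    n = int(round(p.duration_s * p.sample_rate))
    t = np.arange(n) / p.sample_rate
    x = np.zeros(n)
    for frac, name in zip(p.band_fractions, ("brady", "normo", "tachy")):
        if frac <= 0:
            continue
        freq_hz = BAND_CENTER_CPM[name] / 60.0
        amp = np.sqrt(2.0 * frac)  # power = amp^2/2 = frac
        x += amp * np.sin(2 * np.pi * freq_hz * t + rng.uniform(0, 2 * np.pi))
    if p.noise_fraction > 0:
        white = rng.standard_normal(n)
        spectrum = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / p.sample_rate)
        with np.errstate(divide="ignore"):
            weight = np.where(freqs > 0, 1.0 / np.sqrt(freqs), 0.0)
        pink = np.fft.irfft(spectrum * weight, n=n)
        sd = pink.std()
        if sd > 0:
            x += pink / sd * np.sqrt(p.noise_fraction)
    return EGGRecording(x, p.sample_rate, stage="raw")


def simulate_hbct_session(
    beats: BeatSeries, hbct_params: HBCTParams, seed=0, perception_gain=None
) -> HBCTSession:
    """Four counting trials (25/35/45/55 s, shuffled) over a beat series.

    ``perception_gain`` overrides the population-mean gain for this
    participant.  Actual counts are the beats falling in each consecutive
    trial window.
    """
    p = hbct_params
    if beats.duration_s < sum(HBCT_TRIAL_DURATIONS):
        raise InvalidParameterError(
            f"beat series of {beats.duration_s:.0f} s cannot cover "
            f"{sum(HBCT_TRIAL_DURATIONS)} s of trials"
        )
    rng = _rng(seed)
    gain = p.perception_gain if perception_gain is None else perception_gain
    if not 0 <= gain <= 1.5:
        raise InvalidParameterError("perception gain must lie in [0, 1.5]")

    durations = list(HBCT_TRIAL_DURATIONS)
    rng.shuffle(durations)
    times = beats.beat_times_s
    trials = []
    start = 0.0
    for dur in durations:
        actual = int(np.sum((times >= start) & (times < start + dur)))
        reported = gain * actual
        if p.report_noise_sd > 0:
            reported += rng.normal(0, p.report_noise_sd)
        reported = max(int(round(reported)), 0)
        conf = p.confidence_intercept + p.confidence_slope * gain
        if p.confidence_noise_sd > 0:
            conf += rng.normal(0, p.confidence_noise_sd)
        conf = int(np.clip(round(conf), 0, 8))
        trials.append(
            HBCTTrial(
                duration_s=dur,
                actual_count=actual,
                reported_count=reported,
                confidence=conf,
            )
        )
        start += dur
    return HBCTSession(trials)


def _clamp_rating(value, rng, noise_sd):
    if noise_sd > 0:
        value = value + rng.normal(0, noise_sd)
    return float(np.clip(round(value), 1, 7))


def simulate_wlt_record(wlt_params: WLTParams, seed=0) -> WLTRecord:
    """Two-phase volumes plus t0/t1/t2 ratings and negative-affect items."""
    p = wlt_params
    rng = _rng(seed)
    satiation = float(rng.lognormal(p.log_satiation_mean, p.log_satiation_sd))
    additional = float(rng.lognormal(p.log_additional_mean, p.log_additional_sd))
    pct = 100.0 * satiation / (satiation + additional)

    def na_items(mean):
        factor = rng.normal()
        return tuple(
            _clamp_rating(mean + load * factor, rng, p.na_noise_sd)
            for load in p.na_loadings
        )

    t0 = TimepointRatings(
        satiation=_clamp_rating(1.5, rng, p.rating_noise_sd / 2),
        fullness=_clamp_rating(1.5, rng, p.rating_noise_sd / 2),
        na_items=na_items(1.5),
    )
    sat1 = _clamp_rating(p.rating_offset + p.rating_slope * pct, rng, p.rating_noise_sd)
    t1 = TimepointRatings(
        satiation=sat1,
        fullness=_clamp_rating(
            p.rating_offset + p.rating_slope * pct - 0.5, rng, p.rating_noise_sd
        ),
        na_items=na_items(2.2),
    )
    t2 = TimepointRatings(
        satiation=_clamp_rating(5.8, rng, p.rating_noise_sd),
        fullness=_clamp_rating(5.8, rng, p.rating_noise_sd),
        na_items=na_items(p.na_mean_t2),
    )
    return WLTRecord(
        satiation_volume_ml=satiation,
        additional_volume_ml=additional,
        ratings={"t0": t0, "t1": t1, "t2": t2},
    )


def simulate_outcomes(
    features: pd.DataFrame, outcome_params: OutcomeParams, seed=0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate DEBQ outcomes from a known sparse linear model.

    The predictor columns (plus sex) are standardized, multiplied by the
    true coefficient matrix, Gaussian noise is added, and each outcome is
    affinely mapped into the 1-5 DEBQ range.  Returns the feature table
    with outcome columns appended and a frame of the latent (pre-noise)
    outcome values.
    """
    p = outcome_params
    rng = _rng(seed)
    cols = list(p.betas.index)
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise InvalidParameterError(f"feature table lacks predictor columns {missing}")
    if features[cols].isna().any().any():
        raise InvalidParameterError("outcome generation requires complete features")

    X = ip_stats.standardize(features[cols])[cols].to_numpy()
    latents = pd.DataFrame(
        X @ p.betas.to_numpy(), index=features.index, columns=p.betas.columns
    )
    out = features.copy()
    for outcome in p.betas.columns:
        y = latents[outcome].to_numpy().copy()
        if p.residual_sd > 0:
            y = y + rng.normal(0, p.residual_sd, size=len(y))
        latents[f"realized_{outcome}"] = y  # pre-mapping outcome incl. noise
        lo, hi = y.min(), y.max()
        scaled = np.full_like(y, 3.0) if hi == lo else 1.0 + 4.0 * (y - lo) / (hi - lo)
        out[outcome] = scaled
    return out, latents


def apply_missingness(
    cohort: SyntheticCohort, missing_rates: dict, seed=0
) -> SyntheticCohort:
    """Mask instruments completely at random at per-instrument rates.

    A ``dropout`` rate removes all laboratory instruments for the drawn
    participants (questionnaires are kept), mirroring participants who only
    completed the questionnaire part.  Masking nulls both the stored
    instrument objects and the corresponding feature columns; deletions are
    logged one row per (participant, instrument).
    """
    for k, v in missing_rates.items():
        if not 0 <= v < 1:
            raise InvalidParameterError(f"missing rate for {k!r} must lie in [0, 1)")
    rng = _rng(seed)
    ids = list(cohort.participants.index)
    features = cohort.features.copy()
    instruments = {
        "hbct": dict(cohort.hbct_sessions),
        "ecg": dict(cohort.beat_series),
        "egg": dict(cohort.egg_recordings),
        "wlt": dict(cohort.wlt_records),
    }
    log = []

    dropout_rate = missing_rates.get("dropout", 0.0)
    dropped = set()
    if dropout_rate > 0:
        mask = rng.random(len(ids)) < dropout_rate
        dropped = {pid for pid, m in zip(ids, mask) if m}
    for pid in dropped:
        for inst in LAB_INSTRUMENTS:
            instruments[inst][pid] = None
            features.loc[pid, INSTRUMENT_FEATURES[inst]] = np.nan
        log.append({"participant": pid, "instrument": "dropout"})

    for inst in LAB_INSTRUMENTS + ("debq",):
        rate = missing_rates.get(inst, 0.0)
        if rate <= 0:
            continue
        mask = rng.random(len(ids)) < rate
        for pid, m in zip(ids, mask):
            if not m or pid in dropped:
                continue
            if inst == "debq":
                features.loc[pid, INSTRUMENT_FEATURES["debq"]] = np.nan
            else:
                instruments[inst][pid] = None
                features.loc[pid, INSTRUMENT_FEATURES[inst]] = np.nan
            log.append({"participant": pid, "instrument": inst})

    participants = cohort.participants.copy()
    for col in INSTRUMENT_FEATURES["debq"]:
        if col in participants.columns:
            participants[col] = features[col]

    return replace(
        cohort,
        participants=participants,
        beat_series=instruments["ecg"],
        hbct_sessions=instruments["hbct"],
        egg_recordings=instruments["egg"],
        wlt_records=instruments["wlt"],
        features=features,
        missing_log=pd.DataFrame(log, columns=["participant", "instrument"]),
    )


def simulate_cohort(config: CohortConfig = None) -> SyntheticCohort:
    """Generate a complete cohort: signals, sessions, features, outcomes.

    The generation order is fixed so that identical (config, seed) yield
    bit-identical cohorts.  Between-participant heterogeneity comes from
    per-participant draws of the perception gain, LF/HF amplitude scalings
    and gastric band fractions around the configured population values.
    """
    if config is None:
        config = CohortConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    ids = [f"P{i + 1:03d}" for i in range(n)]

    # --- per-participant latent physiology -------------------------------
    hp = config.hbct_params
    gains = np.clip(rng.normal(hp.perception_gain, hp.gain_sd, n), 0.0, 1.5)
    mean_ibis = np.clip(
        rng.normal(config.ibi_params.mean_ibi, config.ibi_params.mean_ibi_sd, n),
        500.0,
        1500.0,
    )
    amp_jitter = rng.lognormal(0.0, 0.35, size=(n, 2))  # LF, HF scalings
    ep = config.egg_params
    base = np.asarray(ep.band_fractions, dtype=float)
    total_frac = base.sum()
    if total_frac > 0:
        conc = 40.0 * base / total_frac + 0.1
        fractions = rng.dirichlet(conc, size=n) * total_frac
    else:
        fractions = np.zeros((n, 3))
    sexes = (rng.random(n) < config.male_fraction).astype(int)  # 1 = male
    heights = rng.normal(1.68, 0.08, n)
    log_bmi = rng.normal(np.log(27.5), 0.23, n)
    weights = np.exp(log_bmi) * heights**2

    beat_series, hbct_sessions, wlt_records, egg_recordings = {}, {}, {}, {}
    rows = []
    for i, pid in enumerate(ids):
        ibi_i = replace(
            config.ibi_params,
            mean_ibi=mean_ibis[i],
            lf_amplitude=config.ibi_params.lf_amplitude * amp_jitter[i, 0],
            hf_amplitude=config.ibi_params.hf_amplitude * amp_jitter[i, 1],
        )
        resting = simulate_ibi_series(ibi_i, config.resting_ecg_duration_s, rng)
        task = simulate_ibi_series(ibi_i, config.task_ecg_duration_s, rng)
        egg_i = replace(ep, band_fractions=tuple(fractions[i]))
        beat_series[pid] = resting
        hbct_sessions[pid] = simulate_hbct_session(
            task, hp, rng, perception_gain=gains[i]
        )
        wlt_records[pid] = simulate_wlt_record(config.wlt_params, rng)
        egg_recordings[pid] = simulate_egg_signal(egg_i, rng)

        rows.append(
            participant_features(
                beat_series=beat_series[pid],
                hbct_session=hbct_sessions[pid],
                wlt_record=wlt_records[pid],
                egg_recording=egg_recordings[pid],
            )
        )

    features = pd.DataFrame(rows, index=pd.Index(ids, name="participant"))
    features[COVARIATE] = sexes
    if features[PREDICTORS].isna().any().any():
        bad = features[PREDICTORS].isna().any(axis=1).sum()
        raise InsufficientDataError(
            f"{bad} simulated participants failed feature extraction"
        )

    features, latents = simulate_outcomes(features, config.outcome_params, rng)

    participants = pd.DataFrame(
        {
            "sex": sexes,
            "height_m": heights,
            "weight_kg": weights,
            **{c: features[c] for c in OUTCOMES},
        },
        index=features.index,
    )

    truth = pd.DataFrame(
        {
            "perception_gain": gains,
            "mean_ibi_ms": mean_ibis,
            "lf_amp_scale": amp_jitter[:, 0],
            "hf_amp_scale": amp_jitter[:, 1],
            "brady_fraction": fractions[:, 0],
            "normo_fraction": fractions[:, 1],
            "tachy_fraction": fractions[:, 2],
            **{
                (c if c.startswith("realized_") else f"latent_{c}"): latents[c]
                for c in latents.columns
            },
        },
        index=features.index,
    )
    ground_truth = GroundTruth(
        per_participant=truth,
        betas=config.outcome_params.betas.copy(),
        residual_sd=config.outcome_params.residual_sd,
        features_complete=features.copy(),
    )

    cohort = SyntheticCohort(
        config=config,
        participants=participants,
        beat_series=beat_series,
        hbct_sessions=hbct_sessions,
        wlt_records=wlt_records,
        egg_recordings=egg_recordings,
        features=features,
        ground_truth=ground_truth,
        missing_log=pd.DataFrame(columns=["participant", "instrument"]),
    )
    if config.missing_rates:
        cohort = apply_missingness(cohort, config.missing_rates, rng)
    return cohort
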