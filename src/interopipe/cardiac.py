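"""Cardiac-domain features.

This module turns an ECG trace or an inter-beat-interval (IBI) series into
the cardiac measures used downstream:

* heartbeat-counting-task (HBCT) accuracy — per-trial
  ``1 - |actual - reported| / actual`` averaged over the four trials,
  clipped at zero so the score stays in [0, 1];
* HBCT confidence — mean of the four 0–8 Likert ratings;
* time-domain heart-rate variability — mean HR (bpm) and RMSSD (ms);
* frequency-domain HRV — LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz) band
  powers of the evenly resampled IBI series and HFnu = 100·HF/(LF+HF).

Artifact handling follows the common local-median rule: intervals deviating
more than a fractional threshold from the median of their neighbourhood are
replaced by linear interpolation; recordings with too many flagged beats are
rejected outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .exceptions import (
    EmptySeriesError,
    InsufficientDataError,
    InvalidParameterError,
    InvalidRatingError,
    RecordingQualityError,
    UndefinedStatisticError,
)

HBCT_TRIAL_DURATIONS = (25, 35, 45, 55)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

__all__ = [
    "BeatSeries",
    "HBCTTrial",
    "HBCTSession",
    "CardiacPhysioFeatures",
    "detect_rpeaks",
    "correct_ibi_artifacts",
    "hbct_accuracy",
    "hbct_confidence",
    "hbct_confidence_variance",
    "time_domain_hrv",
    "frequency_domain_hrv",
    "cardiac_features",
    "HBCT_TRIAL_DURATIONS",
    "LF_BAND",
    "HF_BAND",
]


@dataclass
class BeatSeries:
    """Ordered inter-beat intervals in milliseconds.

    Parameters
    ----------
    intervals : array-like of float
        Successive RR intervals in ms; all strictly positive.
    origin : {'detected', 'provided', 'simulated'}
        Where the beats came from.
    artifact_flags : array-like of bool, optional
        Per-interval artifact marks; defaults to all clean.
    """

    intervals: np.ndarray
    origin: str = "provided"
    artifact_flags: np.ndarray = field(default=None)

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise InvalidParameterError("intervals must be one-dimensional")
        if self.intervals.size and np.any(self.intervals <= 0):
            raise InvalidParameterError("all inter-beat intervals must be > 0 ms")
        if self.origin not in ("detected", "provided", "simulated"):
            raise InvalidParameterError(f"unknown origin {self.origin!r}")
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(self.intervals.size, dtype=bool)
        else:
            self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
            if self.artifact_flags.shape != self.intervals.shape:
                raise InvalidParameterError("artifact_flags must match intervals")

    def __len__(self):
        return self.intervals.size

    @property
    def beat_times_s(self) -> np.ndarray:
        """Cumulative beat times in seconds (first beat at t = first interval)."""
        return np.cumsum(self.intervals) / 1000.0

    @property
    def duration_s(self) -> float:
        return float(self.intervals.sum() / 1000.0)


@dataclass
class HBCTTrial:
    duration_s: int
    actual_count: int
    reported_count: int
    confidence: int

    def __post_init__(self):
        if self.duration_s not in HBCT_TRIAL_DURATIONS:
            raise InvalidParameterError(
                f"trial duration must be one of {HBCT_TRIAL_DURATIONS}, got {self.duration_s}"
            )
        if self.actual_count < 0 or self.reported_count < 0:
            raise InvalidParameterError("heartbeat counts must be non-negative")
        if not (0 <= self.confidence <= 8):
            raise InvalidRatingError(
                f"confidence must lie in 0–8, got {self.confidence}"
            )


@dataclass
class HBCTSession:
    """Four heartbeat-counting trials of 25, 35, 45 and 55 s (any order)."""

    trials: list

    def __post_init__(self):
        if len(self.trials) != 4:
            raise InvalidParameterError("an HBCT session has exactly four trials")
        durations = sorted(t.duration_s for t in self.trials)
        if tuple(durations) != tuple(sorted(HBCT_TRIAL_DURATIONS)):
            raise InvalidParameterError(
                "trials must cover durations 25/35/45/55 s exactly once each"
            )


@dataclass
class CardiacPhysioFeatures:
    mean_hr: float  # beats / min
    rmssd: float  # ms
    hf_power: float  # ms^2
    lf_power: float  # ms^2
    hfnu: float  # % in [0, 100]


def detect_rpeaks(ecg_signal, sample_rate: float) -> BeatSeries:
    """Detect R peaks in a raw ECG trace and return the inter-beat series.

    Band-passes to the QRS range (5–30 Hz), builds a squared-derivative
    energy envelope, thresholds it adaptively and enforces a 250 ms
    refractory period.  The adaptive threshold makes detection invariant to
    overall amplitude scaling.
    """
    x = np.asarray(ecg_signal, dtype=float)
    if sample_rate < 100:
        raise InvalidParameterError("R-peak detection requires sample_rate >= 100 Hz")
    if x.size < 10 * sample_rate:
        raise InsufficientDataError("need at least 10 s of ECG for beat detection")

    sos = signal.butter(2, [5.0, 30.0], btype="bandpass", fs=sample_rate, output="sos")
    filt = signal.sosfiltfilt(sos, x)
    envelope = np.gradient(filt) ** 2
    # smooth over ~120 ms (QRS width scale)
    win = max(int(0.12 * sample_rate), 1)
    envelope = np.convolve(envelope, np.ones(win) / win, mode="same")

    peak_level = np.percentile(envelope, 99)
    if peak_level <= 0:
        raise EmptySeriesError("flat signal: no QRS energy found")
    threshold = 0.3 * peak_level
    distance = int(0.25 * sample_rate)  # 250 ms refractory
    peaks, _ = signal.find_peaks(envelope, height=threshold, distance=distance)
    if peaks.size < 2:
        raise EmptySeriesError("fewer than two R peaks detected")
    intervals_ms = np.diff(peaks) / sample_rate * 1000.0
    return BeatSeries(intervals_ms, origin="detected")


def correct_ibi_artifacts(
    series: BeatSeries,
    deviation_threshold: float = 0.25,
    window: int = 11,
    reject_fraction: float = 0.20,
) -> BeatSeries:
    """Replace artifactual intervals by linear interpolation.

    An interval is flagged when it deviates from the median of its
    ``window`` neighbours by more than ``deviation_threshold`` (fractional).
    Flagged intervals are linearly interpolated between the nearest clean
    neighbours.  If more than ``reject_fraction`` of intervals are flagged
    the recording is rejected as unusable.
    """
    if len(series) < 3:
        raise InsufficientDataError("artifact correction needs at least 3 intervals")
    if not 0 < deviation_threshold:
        raise InvalidParameterError("deviation_threshold must be positive")

    iv = series.intervals
    k = window if window % 2 else window + 1
    k = min(k, len(series) if len(series) % 2 else len(series) - 1)
    local_median = signal.medfilt(iv, kernel_size=k)
    # medfilt zero-pads the edges; fall back to the global median there
    half = k // 2
    edge_med = np.median(iv)
    if half > 0:
        local_median[:half] = edge_med
        local_median[-half:] = edge_med
    flags = np.abs(iv - local_median) > deviation_threshold * local_median

    n_flagged = int(flags.sum())
    if n_flagged > reject_fraction * len(series):
        raise RecordingQualityError(
            f"{n_flagged}/{len(series)} intervals flagged as artifacts "
            f"(> {reject_fraction:.0%}); recording rejected"
        )
    if n_flagged == 0:
        return BeatSeries(iv.copy(), origin=series.origin)

    clean_idx = np.flatnonzero(~flags)
    if clean_idx.size == 0:
        raise RecordingQualityError("no clean intervals to interpolate from")
    corrected = iv.copy()
    corrected[flags] = np.interp(np.flatnonzero(flags), clean_idx, iv[clean_idx])
    return BeatSeries(corrected, origin=series.origin)


def hbct_accuracy(session: HBCTSession) -> float:
    """Mean heartbeat-counting accuracy over the four trials, in [0, 1].

    Per trial: ``1 - |actual - reported| / actual``, clipped below at 0 so
    gross over-reporting cannot drive the score negative.
    """
    scores = []
    for trial in session.trials:
        if trial.actual_count == 0:
            raise UndefinedStatisticError(
                "trial accuracy undefined: actual heartbeat count is zero"
            )
        score = 1.0 - abs(trial.actual_count - trial.reported_count) / trial.actual_count
        scores.append(max(score, 0.0))
    return float(np.mean(scores))


def hbct_confidence(session: HBCTSession) -> float:
    """Mean of the four 0–8 confidence ratings."""
    ratings = [t.confidence for t in session.trials]
    for r in ratings:
        if not (0 <= r <= 8):
            raise InvalidRatingError(f"confidence rating {r} outside 0–8")
    return float(np.mean(ratings))


def hbct_confidence_variance(session: HBCTSession) -> float:
    """Sample variance of the four confidence ratings.

    Zero variance is worth flagging before any within-person
    confidence-accuracy correlation: such a correlation is undefined when
    the participant gives the same rating on every trial, which is one
    reason the difference-score insight is used instead.
    """
    return float(np.var([t.confidence for t in session.trials], ddof=1))


def time_domain_hrv(series: BeatSeries) -> tuple[float, float]:
    """Return (mean_hr in bpm, RMSSD in ms).

    mean_hr = 60000 / mean(intervals); RMSSD is the root mean square of
    successive interval differences.
    """
    if len(series) < 2:
        raise InsufficientDataError("time-domain HRV needs at least 2 intervals")
    iv = series.intervals
    mean_hr = 60000.0 / float(iv.mean())
    rmssd = float(np.sqrt(np.mean(np.diff(iv) ** 2)))
    return mean_hr, rmssd


def frequency_domain_hrv(
    series: BeatSeries, resample_rate: float = 4.0
) -> tuple[float, float, float]:
    """Return (hf_power, lf_power, hfnu) from the resampled IBI series.

    The irregular RR series is interpolated onto an even 4 Hz grid with a
    cubic spline over cumulative beat times, mean-centred, and its spectrum
    estimated with a Welch averaged periodogram.  LF is integrated over
    0.04–0.15 Hz, HF over 0.15–0.40 Hz, and HFnu = 100·HF/(LF+HF).
    """
    if series.duration_s < 120:
        raise InsufficientDataError(
            "frequency-domain HRV needs a series spanning at least 120 s"
        )
    times = series.beat_times_s
    spline = CubicSpline(times, series.intervals)
    grid = np.arange(times[0], times[-1], 1.0 / resample_rate)
    rr = spline(grid)
    rr = rr - rr.mean()

    nperseg = min(rr.size, int(128 * resample_rate))
    freqs, psd = signal.welch(rr, fs=resample_rate, window="hann", nperseg=nperseg)

    def band_power(lo, hi):
        mask = (freqs >= lo) & (freqs < hi)
        return float(np.trapezoid(psd[mask], freqs[mask])) if mask.sum() > 1 else 0.0

    lf = band_power(*LF_BAND)
    hf = band_power(*HF_BAND)
    total = lf + hf
    if total <= 0:
        raise UndefinedStatisticError("no spectral power in the LF+HF range")
    hfnu = 100.0 * hf / total
    return hf, lf, hfnu


def cardiac_features(series: BeatSeries) -> CardiacPhysioFeatures:
    """Convenience wrapper: artifact-correct then compute all HRV features."""
    corrected = correct_ibi_artifacts(series)
    mean_hr, rmssd = time_domain_hrv(corrected)
    hf, lf, hfnu = frequency_domain_hrv(corrected)
    return CardiacPhysioFeatures(
        mean_hr=mean_hr, rmssd=rmssd, hf_power=hf, lf_power=lf, hfnu=hfnu
    )
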