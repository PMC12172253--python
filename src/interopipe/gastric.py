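"""Gastric-domain features.

Electrogastrogram (EGG) processing and water-load-test (WLT-II) scoring.

The EGG pipeline mirrors the standard cutaneous-EGG workflow: zero-phase
band-pass to the gastric range 0.016–0.25 Hz (1–15 cycles per minute, cpm),
downsampling to 10 Hz, then spectral estimation over 240-s runs with 75 %
overlap, each run Hann-tapered and zero-padded to the next power of two.
Band powers are integrated over bradygastria (1.0–2.5 cpm), normogastria
(2.5–3.75 cpm) and tachygastria (3.75–10.0 cpm) and expressed as percentages
of the total power in the full 1–15 cpm filter range — so the three
percentages sum to at most 100, with the 10–15 cpm remainder unassigned.

The WLT-II side scores the two-phase drinking volumes (satiation volume,
additional volume to maximum fullness, their total, and satiation as a
percentage of maximum fullness) and the questionnaire ratings: satiation and
fullness on 1–7 scales and a five-item negative-affect scale (guilt, nausea,
discomfort, sluggishness, arousal) whose internal consistency is assessed
with Cronbach's alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    InvalidRatingError,
    MissingDataError,
    UndefinedStatisticError,
)

#: Gastric frequency bands in cycles per minute, half-open [low, high).
CPM_BANDS = {
    "brady": (1.0, 2.5),
    "normo": (2.5, 3.75),
    "tachy": (3.75, 10.0),
}
FILTER_RANGE_CPM = (1.0, 15.0)
EGG_TARGET_RATE = 10.0  # Hz after downsampling
EGG_RUN_SECONDS = 240.0
EGG_RUN_OVERLAP = 0.75
NA_ITEMS = ("guilt", "nausea", "discomfort", "sluggishness", "arousal")

__all__ = [
    "EGGRecording",
    "SpectralBands",
    "TimepointRatings",
    "WLTRecord",
    "WLTIndices",
    "preprocess_egg",
    "egg_band_powers",
    "wlt_indices",
    "score_wlt_questionnaire",
    "cronbach_alpha",
    "CPM_BANDS",
    "NA_ITEMS",
]


@dataclass
class EGGRecording:
    """Uniformly sampled gastric myoelectric trace (arbitrary units)."""

    samples: np.ndarray
    sample_rate: float
    stage: str = "raw"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidParameterError("EGG samples must be one-dimensional")
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")
        if self.stage not in ("raw", "preprocessed"):
            raise InvalidParameterError(f"unknown stage {self.stage!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class SpectralBands:
    """Percentage of total 1–15 cpm power in each gastric band."""

    brady_pct: float
    normo_pct: float
    tachy_pct: float
    total_power: float

    def __post_init__(self):
        for name in ("brady_pct", "normo_pct", "tachy_pct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0 + 1e-9):
                raise InvalidParameterError(f"{name} = {v} outside [0, 100]")


@dataclass
class TimepointRatings:
    """WLT-II questionnaire ratings at one timepoint (all 1–7)."""

    satiation: float
    fullness: float
    na_items: tuple  # five ratings, order per NA_ITEMS

    def __post_init__(self):
        self.na_items = tuple(float(v) for v in self.na_items)
        if len(self.na_items) != len(NA_ITEMS):
            raise InvalidParameterError(
                f"negative-affect scale has {len(NA_ITEMS)} items"
            )
        for label, v in (
            ("satiation", self.satiation),
            ("fullness", self.fullness),
            *zip(NA_ITEMS, self.na_items),
        ):
            if not (1 <= v <= 7):
                raise InvalidRatingError(f"{label} rating {v} outside 1–7")


@dataclass
class WLTRecord:
    """Two-phase water-load volumes plus questionnaire ratings at t0/t1/t2."""

    satiation_volume_ml: float
    additional_volume_ml: float
    ratings: dict = field(default_factory=dict)  # keys 't0', 't1', 't2'

    def __post_init__(self):
        if self.satiation_volume_ml < 0 or self.additional_volume_ml < 0:
            raise InvalidParameterError("ingested volumes must be non-negative")
        for key in self.ratings:
            if key not in ("t0", "t1", "t2"):
                raise InvalidParameterError(f"unknown timepoint {key!r}")

    @property
    def total_volume_ml(self) -> float:
        return self.satiation_volume_ml + self.additional_volume_ml


@dataclass
class WLTIndices:
    satiation_volume_ml: float
    additional_volume_ml: float
    total_volume_ml: float
    pct_satiation_of_max: float


def preprocess_egg(rec: EGGRecording) -> EGGRecording:
    """Band-pass, downsample and mean-centre a raw EGG recording.

    Zero-phase Butterworth band-pass over 0.016–0.25 Hz at the native rate,
    linear interpolation of any flagged (NaN) gaps, resampling onto a 10 Hz
    grid, and mean removal.  The 0.25 Hz low-pass sits far below the 5 Hz
    Nyquist of the target rate, so no separate anti-alias stage is needed.
    """
    if rec.stage != "raw":
        raise InvalidParameterError("preprocess_egg expects a raw recording")
    if rec.duration_s < EGG_RUN_SECONDS:
        raise InsufficientDataError(
            f"EGG of {rec.duration_s:.0f} s is shorter than one "
            f"{EGG_RUN_SECONDS:.0f}-s analysis run"
        )
    if rec.sample_rate < 20:
        raise InvalidParameterError(
            "native rate below 20 Hz risks aliasing; record faster or "
            "pre-filter externally"
        )

    x = rec.samples.astype(float)
    if np.isnan(x).any():  # flagged gaps
        idx = np.arange(x.size)
        good = ~np.isnan(x)
        if good.sum() < 2:
            raise InsufficientDataError("EGG recording is almost entirely gaps")
        x = np.interp(idx, idx[good], x[good])

    low, high = 0.016, 0.25
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rec.sample_rate, output="sos")
    x = signal.sosfiltfilt(sos, x)

    t_native = np.arange(x.size) / rec.sample_rate
    t_target = np.arange(0, t_native[-1], 1.0 / EGG_TARGET_RATE)
    y = np.interp(t_target, t_native, x)
    y = y - y.mean()
    return EGGRecording(y, EGG_TARGET_RATE, stage="preprocessed")


def egg_band_powers(rec: EGGRecording) -> SpectralBands:
    """Average periodogram over 240-s runs and integrate the cpm bands.

    The preprocessed 10 Hz trace is split into 240-s runs stepping 60 s
    (75 % overlap).  Each run is Hann-tapered, zero-padded to the next power
    of two, and its periodogram computed; periodograms are averaged across
    runs.  Band powers are the sums over [low, high) cpm bins and reported
    as percentages of the total 1–15 cpm power.
    """
    if rec.stage != "preprocessed":
        raise InvalidParameterError("egg_band_powers expects a preprocessed recording")
    fs = rec.sample_rate
    run_len = int(round(EGG_RUN_SECONDS * fs))
    step = int(round(run_len * (1.0 - EGG_RUN_OVERLAP)))
    x = rec.samples
    if x.size < run_len:
        raise InsufficientDataError("need at least one full 240-s run")

    nfft = 1 << (run_len - 1).bit_length()  # next power of two
    window = np.hanning(run_len)
    starts = range(0, x.size - run_len + 1, step)
    psd = np.zeros(nfft // 2 + 1)
    for s in starts:
        seg = x[s : s + run_len] * window
        spectrum = np.fft.rfft(seg, n=nfft)
        psd += np.abs(spectrum) ** 2
    psd /= len(list(starts))

    cpm = np.fft.rfftfreq(nfft, d=1.0 / fs) * 60.0

    def band_sum(lo, hi):
        return float(psd[(cpm >= lo) & (cpm < hi)].sum())

    total = band_sum(*FILTER_RANGE_CPM)
    if total <= 0:
        raise UndefinedStatisticError("no power in the 1–15 cpm range")
    pct = {name: 100.0 * band_sum(*edges) / total for name, edges in CPM_BANDS.items()}
    return SpectralBands(
        brady_pct=pct["brady"],
        normo_pct=pct["normo"],
        tachy_pct=pct["tachy"],
        total_power=total,
    )


def wlt_indices(rec: WLTRecord) -> WLTIndices:
    """Volume indices of the two-step water load test.

    ``pct_satiation_of_max`` is the satiation volume as a percentage of the
    total (maximum-fullness) volume.
    """
    total = rec.total_volume_ml
    if total <= 0:
        raise UndefinedStatisticError(
            "percentage of satiation undefined: total ingested volume is zero"
        )
    return WLTIndices(
        satiation_volume_ml=rec.satiation_volume_ml,
        additional_volume_ml=rec.additional_volume_ml,
        total_volume_ml=total,
        pct_satiation_of_max=100.0 * rec.satiation_volume_ml / total,
    )


def score_wlt_questionnaire(
    rec: WLTRecord, timepoint: str = "t2"
) -> tuple[float, float, float]:
    """Return (satiation, fullness, negative_affect) at one timepoint.

    Satiation and fullness are passed through; negative affect is the mean
    of the five NA items.  The post-ingestion timepoint t2 is the default
    analysis point.
    """
    if timepoint not in rec.ratings:
        raise MissingDataError(f"no ratings recorded at timepoint {timepoint!r}")
    r = rec.ratings[timepoint]
    return float(r.satiation), float(r.fullness), float(np.mean(r.na_items))


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha of an items × respondents score matrix.

    ``item_matrix`` is (n_respondents, k_items).  alpha =
    (k/(k-1)) * (1 - sum of item variances / variance of row sums), with
    sample (n-1) variances.
    """
    m = np.asarray(item_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise InvalidParameterError("alpha needs a 2-D matrix with >= 2 items")
    if m.shape[0] < 3:
        raise InsufficientDataError("alpha needs at least 3 respondents")
    if np.isnan(m).any():
        raise MissingDataError("alpha requires complete item responses")
    k = m.shape[1]
    item_vars = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise UndefinedStatisticError("total-score variance is zero")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))
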