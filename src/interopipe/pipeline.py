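"""Orchestration and file I/O: cohort serialization, ingest with validation,
and the end-to-end analysis run.

On-disk layout (all plain text, produced by ``interopipe simulate`` and
consumed by the analysis stages)::

    <dir>/participants.csv      id, sex, height, weight, DEBQ outcomes
    <dir>/hbct.csv              one row per counting trial
    <dir>/wlt.csv               volumes + ratings wide, one row per participant
    <dir>/signals/ibi_<id>.csv  one inter-beat interval (ms) per row
    <dir>/signals/egg_<id>.csv  one EGG sample per row
    <dir>/signals/egg_<id>.json sidecar: {"sample_rate_hz": ..., "units": ...}
    <dir>/ground_truth.csv      generator ground truth (never read back by
                                the analysis)

``run_full_analysis`` ties the stages together: ingest -> per-participant
feature extraction -> extended feature table -> VIF screening -> per-outcome
OLS/LASSO comparison on shared folds -> report.  Everything downstream of
the inputs is a pure function of (files, config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cardiac import BeatSeries, HBCTSession, HBCTTrial
from .cohort import SyntheticCohort
from .exceptions import (
    FormatError,
    InsufficientDataError,
    InvalidParameterError,
)
from .features import participant_features
from .gastric import EGGRecording, NA_ITEMS, TimepointRatings, WLTRecord
from .model import InteroceptionModel
from .scoring import (
    COVARIATE,
    DEFAULT_DIMENSION_MAP,
    OUTCOMES,
    PREDICTORS,
    assemble_feature_table,
    vif_screen,
)

#: predictors entering the multicollinearity screen (the full pre-screening
#: variable set: all WLT volume indices and all three EGG bands)
EXTENDED_PREDICTORS = PREDICTORS + [
    "satiation_volume_ml",
    "additional_volume_ml",
    "total_volume_ml",
    "brady_pct",
    "tachy_pct",
]

TIMEPOINTS = ("t0", "t1", "t2")

__all__ = [
    "RunConfig",
    "RunReport",
    "write_cohort",
    "read_signal",
    "read_ibi",
    "read_egg",
    "read_tables",
    "extract_features",
    "analyze_features",
    "run_full_analysis",
    "render_report",
    "EXTENDED_PREDICTORS",
]


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str = None
    folds: int = 10
    repeats: int = 1
    seed: int = 0
    vif_threshold: float = 10.0
    gastric_rating_timepoint: str = "t1"
    lambda_grid: np.ndarray = None
    outcomes: tuple = tuple(OUTCOMES)

    def __post_init__(self):
        if self.folds < 2:
            raise InvalidParameterError("folds must be >= 2")
        if self.gastric_rating_timepoint not in TIMEPOINTS:
            raise InvalidParameterError(
                f"timepoint must be one of {TIMEPOINTS}"
            )


@dataclass
class RunReport:
    n_input: int
    n_complete: int
    exclusions: dict  # reason -> count
    descriptives: pd.DataFrame  # n/mean/sd/min/max per variable
    screening_vif: dict
    screening_excluded: list
    screening_retained: list
    coefficient_tables: dict  # outcome -> DataFrame
    cv_comparisons: dict  # outcome -> DataFrame (ols/lasso x r2/rmse/mae)
    verdicts: dict  # outcome -> 'lasso' or 'ols' (better out-of-fold RMSE)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_complete": self.n_complete,
            "exclusions": dict(self.exclusions),
            "descriptives": _frame_to_dict(self.descriptives),
            "screening": {
                "vif": {k: _num(v) for k, v in self.screening_vif.items()},
                "excluded": [list(e) for e in self.screening_excluded],
                "retained": list(self.screening_retained),
            },
            "coefficients": {
                k: _frame_to_dict(v) for k, v in self.coefficient_tables.items()
            },
            "cv": {k: _frame_to_dict(v) for k, v in self.cv_comparisons.items()},
            "verdicts": dict(self.verdicts),
            "seed": self.seed,
        }


def _num(v):
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    if isinstance(v, float) and not np.isfinite(v):
        return None if np.isnan(v) else ("inf" if v > 0 else "-inf")
    return v


def _frame_to_dict(df: pd.DataFrame) -> dict:
    return {
        str(idx): {str(c): _num(v) for c, v in row.items()}
        for idx, row in df.iterrows()
    }


# ---------------------------------------------------------------------------
# serialization


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write a synthetic cohort as CSV tables plus per-participant signals."""
    out = Path(out_dir)
    (out / "signals").mkdir(parents=True, exist_ok=True)

    cohort.participants.to_csv(out / "participants.csv")

    hbct_rows = []
    for pid, session in cohort.hbct_sessions.items():
        if session is None:
            continue
        for k, t in enumerate(session.trials):
            hbct_rows.append(
                {
                    "participant": pid,
                    "trial": k,
                    "duration_s": t.duration_s,
                    "actual_count": t.actual_count,
                    "reported_count": t.reported_count,
                    "confidence": t.confidence,
                }
            )
    pd.DataFrame(hbct_rows).to_csv(out / "hbct.csv", index=False)

    wlt_rows = []
    for pid, rec in cohort.wlt_records.items():
        if rec is None:
            continue
        row = {
            "participant": pid,
            "satiation_volume_ml": rec.satiation_volume_ml,
            "additional_volume_ml": rec.additional_volume_ml,
        }
        for tp in TIMEPOINTS:
            r = rec.ratings[tp]
            row[f"satiation_{tp}"] = r.satiation
            row[f"fullness_{tp}"] = r.fullness
            for item, value in zip(NA_ITEMS, r.na_items):
                row[f"na_{item}_{tp}"] = value
        wlt_rows.append(row)
    pd.DataFrame(wlt_rows).to_csv(out / "wlt.csv", index=False)

    for pid, series in cohort.beat_series.items():
        if series is None:
            continue
        pd.DataFrame({"interval_ms": series.intervals}).to_csv(
            out / "signals" / f"ibi_{pid}.csv", index=False, float_format="%.17g"
        )
    for pid, rec in cohort.egg_recordings.items():
        if rec is None:
            continue
        pd.DataFrame({"sample": rec.samples}).to_csv(
            out / "signals" / f"egg_{pid}.csv", index=False, float_format="%.8g"
        )
        (out / "signals" / f"egg_{pid}.json").write_text(
            json.dumps({"sample_rate_hz": rec.sample_rate, "units": "au"})
        )

    truth = cohort.ground_truth.per_participant.copy()
    truth.to_csv(out / "ground_truth.csv")
    cohort.ground_truth.betas.to_csv(out / "ground_truth_betas.csv")
    return out


# ---------------------------------------------------------------------------
# ingest


def read_signal(path, sidecar_path) -> tuple[np.ndarray, float]:
    """Read a sampled signal CSV plus its JSON sidecar.

    Returns (samples, sample_rate_hz).  The sidecar must declare a positive
    ``sample_rate_hz``; an optional ``time_s`` column must be strictly
    increasing.
    """
    path, sidecar_path = Path(path), Path(sidecar_path)
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar {sidecar_path} is not valid JSON: {exc}") from exc
    rate = meta.get("sample_rate_hz")
    if rate is None or not (isinstance(rate, (int, float)) and rate > 0):
        raise FormatError(f"sidecar {sidecar_path} lacks a positive sample_rate_hz")

    df = pd.read_csv(path, float_precision="round_trip")
    if "sample" not in df.columns:
        raise FormatError(f"{path}: expected a 'sample' column")
    samples = pd.to_numeric(df["sample"], errors="coerce")
    if samples.isna().all():
        raise FormatError(f"{path}: sample column is not numeric")
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise FormatError(f"{path}: time column is not strictly increasing")
    return samples.to_numpy(dtype=float), float(rate)


def read_egg(path, sidecar_path) -> EGGRecording:
    samples, rate = read_signal(path, sidecar_path)
    return EGGRecording(samples, rate, stage="raw")


def read_ibi(path) -> BeatSeries:
    """Read an inter-beat series CSV (one interval in ms per row)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "interval_ms" not in df.columns:
        raise FormatError(f"{path}: expected an 'interval_ms' column")
    return BeatSeries(df["interval_ms"].to_numpy(dtype=float), origin="provided")


def read_tables(input_dir) -> dict:
    """Ingest the instrument CSVs and signals of one cohort directory.

    Returns a dict with participants (DataFrame) and per-participant
    instrument objects (None where an instrument is missing).  Cell
    validation is delegated to the domain constructors, so a bad rating
    raises with the participant id in the message.
    """
    d = Path(input_dir)
    ppath = d / "participants.csv"
    if not ppath.exists():
        raise FormatError(f"no participants.csv in {d}")
    participants = pd.read_csv(ppath, index_col=0)
    if participants.empty:
        raise InsufficientDataError("participants table is empty")
    ids = list(participants.index)

    hbct = {pid: None for pid in ids}
    hpath = d / "hbct.csv"
    if hpath.exists():
        hdf = pd.read_csv(hpath)
        if len(hdf):
            for pid, grp in hdf.groupby("participant"):
                try:
                    trials = [
                        HBCTTrial(
                            duration_s=int(r.duration_s),
                            actual_count=int(r.actual_count),
                            reported_count=int(r.reported_count),
                            confidence=int(r.confidence),
                        )
                        for r in grp.itertuples()
                    ]
                    hbct[pid] = HBCTSession(trials)
                except InvalidParameterError as exc:
                    raise FormatError(f"hbct.csv, participant {pid}: {exc}") from exc

    wlt = {pid: None for pid in ids}
    wpath = d / "wlt.csv"
    if wpath.exists():
        wdf = pd.read_csv(wpath)
        for r in wdf.itertuples():
            pid = r.participant
            try:
                ratings = {}
                for tp in TIMEPOINTS:
                    ratings[tp] = TimepointRatings(
                        satiation=getattr(r, f"satiation_{tp}"),
                        fullness=getattr(r, f"fullness_{tp}"),
                        na_items=tuple(
                            getattr(r, f"na_{item}_{tp}") for item in NA_ITEMS
                        ),
                    )
                wlt[pid] = WLTRecord(
                    satiation_volume_ml=r.satiation_volume_ml,
                    additional_volume_ml=r.additional_volume_ml,
                    ratings=ratings,
                )
            except InvalidParameterError as exc:
                raise FormatError(f"wlt.csv, participant {pid}: {exc}") from exc

    ibi = {pid: None for pid in ids}
    egg = {pid: None for pid in ids}
    sig = d / "signals"
    for pid in ids:
        f = sig / f"ibi_{pid}.csv"
        if f.exists():
            ibi[pid] = read_ibi(f)
        f = sig / f"egg_{pid}.csv"
        if f.exists():
            egg[pid] = read_egg(f, sig / f"egg_{pid}.json")

    return {
        "participants": participants,
        "hbct": hbct,
        "wlt": wlt,
        "ibi": ibi,
        "egg": egg,
    }


# ---------------------------------------------------------------------------
# analysis


def extract_features(tables: dict, gastric_rating_timepoint="t1") -> pd.DataFrame:
    """Per-participant feature table (NaN where instruments are missing)."""
    participants = tables["participants"]
    rows = {}
    for pid in participants.index:
        rows[pid] = participant_features(
            beat_series=tables["ibi"].get(pid),
            hbct_session=tables["hbct"].get(pid),
            wlt_record=tables["wlt"].get(pid),
            egg_recording=tables["egg"].get(pid),
            gastric_rating_timepoint=gastric_rating_timepoint,
        )
    features = pd.DataFrame.from_dict(rows, orient="index")
    features.index.name = "participant"
    features[COVARIATE] = participants["sex"]
    for c in OUTCOMES:
        if c in participants.columns:
            features[c] = participants[c]
    return features


def analyze_features(
    features: pd.DataFrame,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    vif_threshold: float = 10.0,
    dimension_map=None,
    lambda_grid=None,
    outcomes=tuple(OUTCOMES),
) -> RunReport:
    """Screen, fit and compare on an already-extracted feature table."""
    n_input = len(features)
    screen_cols = [c for c in EXTENDED_PREDICTORS if c in features.columns]
    required = screen_cols + [COVARIATE] + list(outcomes)
    complete = assemble_feature_table(features, required_columns=required)
    n_complete = len(complete)
    if n_complete < 2 * folds:
        raise InvalidParameterError(
            f"{folds}-fold cross-validation needs at least {2 * folds} complete "
            f"cases, found {n_complete}"
        )

    screening = vif_screen(
        complete,
        predictors=screen_cols,
        threshold=vif_threshold,
        dimension_map=DEFAULT_DIMENSION_MAP if dimension_map is None else dimension_map,
    )

    desc = complete[screen_cols + [COVARIATE] + list(outcomes)]
    descriptives = pd.DataFrame(
        {
            "n": features[desc.columns].notna().sum(),
            "mean": desc.mean(),
            "sd": desc.std(ddof=1),
            "min": desc.min(),
            "max": desc.max(),
        }
    )

    coefficient_tables, cv_comparisons, verdicts = {}, {}, {}
    for outcome in outcomes:
        model = InteroceptionModel(
            complete, outcome, predictors=screening.retained, covariates=[COVARIATE]
        )
        res = model.fit(folds=folds, repeats=repeats, seed=seed, lambda_grid=lambda_grid)
        coefficient_tables[outcome] = res.coefficient_table()
        cv_comparisons[outcome] = res.cv_comparison()
        verdicts[outcome] = "lasso" if res.lasso_outperforms else "ols"

    return RunReport(
        n_input=n_input,
        n_complete=n_complete,
        exclusions={"listwise_missing": n_input - n_complete},
        descriptives=descriptives,
        screening_vif=screening.vif,
        screening_excluded=screening.excluded,
        screening_retained=screening.retained,
        coefficient_tables=coefficient_tables,
        cv_comparisons=cv_comparisons,
        verdicts=verdicts,
        seed=seed,
    )


def run_full_analysis(config: RunConfig) -> RunReport:
    """Ingest a cohort directory and run the complete analysis."""
    tables = read_tables(config.input_dir)
    features = extract_features(
        tables, gastric_rating_timepoint=config.gastric_rating_timepoint
    )
    report = analyze_features(
        features,
        folds=config.folds,
        repeats=config.repeats,
        seed=config.seed,
        vif_threshold=config.vif_threshold,
        lambda_grid=config.lambda_grid,
        outcomes=config.outcomes,
    )
    if config.output_dir is not None:
        render_report(report, config.output_dir)
    return report


def render_report(report: RunReport, out_dir, formats=("json", "text")) -> list:
    """Write the report as machine-readable JSON and a readable table file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if "json" in formats:
        path = out / "report.json"
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        written.append(path)
    if "text" in formats:
        lines = [
            f"Participants: {report.n_input} input, {report.n_complete} complete "
            f"({report.exclusions.get('listwise_missing', 0)} removed listwise)",
            "",
            "Descriptive statistics",
            report.descriptives.round(2).to_string(),
            "",
            "Multicollinearity screening",
            "  retained: " + ", ".join(report.screening_retained),
        ]
        for name, reason in report.screening_excluded:
            lines.append(f"  excluded: {name} ({reason})")
        for outcome, table in report.coefficient_tables.items():
            lines += [
                "",
                f"Outcome: {outcome}",
                table.round(4).to_string(),
                "",
                "  cross-validated prediction:",
                report.cv_comparisons[outcome].round(4).to_string(),
                f"  better out-of-fold RMSE: {report.verdicts[outcome]}",
            ]
        path = out / "report.txt"
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    return written
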