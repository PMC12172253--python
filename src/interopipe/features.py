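"""Per-participant feature extraction.

Maps one participant's instruments (IBI series, HBCT session, WLT record,
EGG recording) onto the scalar features consumed by the regression stage.
Missing instruments yield NaN features, which the feature-table assembly
later removes by listwise deletion.
"""

from __future__ import annotations

import numpy as np

from . import cardiac, gastric, scoring
from .exceptions import InteropipeError

#: feature columns produced per instrument (used for missingness masking too)
INSTRUMENT_FEATURES = {
    "hbct": ["hbct_accuracy", "hbct_confidence", "cardiac_insight"],
    "ecg": ["mean_hr", "rmssd", "hfnu"],
    "egg": ["brady_pct", "normo_pct", "tachy_pct"],
    "wlt": [
        "satiation_volume_ml",
        "additional_volume_ml",
        "total_volume_ml",
        "pct_satiation_of_max",
        "satiation_t2",
        "fullness_t2",
        "negative_affect_t2",
        "gastric_insight",
    ],
    "debq": ["debq_emotional", "debq_external", "debq_restrained"],
}

ALL_FEATURES = [f for feats in INSTRUMENT_FEATURES.values() for f in feats]


def participant_features(
    beat_series=None,
    hbct_session=None,
    wlt_record=None,
    egg_recording=None,
    gastric_rating_timepoint: str = "t1",
) -> dict:
    """Extract every available feature for one participant.

    Parameters left as None (missing instruments) produce NaN for the
    features they would supply.  ``gastric_rating_timepoint`` selects the
    satiation rating paired with the WLT percentage index for gastric
    insight (t1, the end of the satiation drinking phase, by default).
    """
    row = {name: np.nan for name in ALL_FEATURES if not name.startswith("debq")}

    if hbct_session is not None:
        acc = cardiac.hbct_accuracy(hbct_session)
        conf = cardiac.hbct_confidence(hbct_session)
        row["hbct_accuracy"] = acc
        row["hbct_confidence"] = conf
        acc_pomp = scoring.pomp(acc, *scoring.POMP_BOUNDS["hbct_accuracy"])
        conf_pomp = scoring.pomp(conf, *scoring.POMP_BOUNDS["hbct_confidence"])
        row["cardiac_insight"] = scoring.insight_score(acc_pomp, conf_pomp).value

    if beat_series is not None:
        try:
            phys = cardiac.cardiac_features(beat_series)
        except InteropipeError:
            phys = None  # quality rejection leaves the features missing
        if phys is not None:
            row["mean_hr"] = phys.mean_hr
            row["rmssd"] = phys.rmssd
            row["hfnu"] = phys.hfnu

    if egg_recording is not None:
        rec = egg_recording
        try:
            if rec.stage == "raw":
                rec = gastric.preprocess_egg(rec)
            bands = gastric.egg_band_powers(rec)
        except InteropipeError:
            bands = None
        if bands is not None:
            row["brady_pct"] = bands.brady_pct
            row["normo_pct"] = bands.normo_pct
            row["tachy_pct"] = bands.tachy_pct

    if wlt_record is not None:
        idx = gastric.wlt_indices(wlt_record)
        row["satiation_volume_ml"] = idx.satiation_volume_ml
        row["additional_volume_ml"] = idx.additional_volume_ml
        row["total_volume_ml"] = idx.total_volume_ml
        row["pct_satiation_of_max"] = idx.pct_satiation_of_max
        sat2, full2, na2 = gastric.score_wlt_questionnaire(wlt_record, "t2")
        row["satiation_t2"] = sat2
        row["fullness_t2"] = full2
        row["negative_affect_t2"] = na2
        if gastric_rating_timepoint in wlt_record.ratings:
            rating = wlt_record.ratings[gastric_rating_timepoint].satiation
            row["gastric_insight"] = scoring.gastric_insight(idx, rating).value

    return row
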