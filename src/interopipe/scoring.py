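"""Composite scoring: POMP rescaling, interoceptive insight, BMI, DEBQ
subscales, feature-table assembly and multicollinearity screening.

Interoceptive *insight* quantifies metacognitive correspondence between an
objective measure (e.g. heartbeat-counting accuracy) and a self-report
measure (e.g. confidence).  Both are first mapped onto a common 0–100 scale
with the Percent-Of-Maximum-Possible (POMP) transform

    POMP(x) = (x - scale_min) / (scale_max - scale_min) * 100,

using the theoretical instrument bounds (accuracy 0–1, confidence 0–8,
satiation rating 1–7, percentages 0–100), and insight is

    insight = 100 - |POMP(self-report) - POMP(accuracy)|,

so 100 means perfect correspondence and 0 maximal mismatch.  Unlike a
within-person correlation, this difference score is defined even when
confidence has zero variance across trials and it penalises absolute
miscalibration, not just lack of covariation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    AliasingError,
    InsufficientDataError,
    InvalidParameterError,
    InvalidRatingError,
)
from .gastric import WLTIndices

logger = logging.getLogger(__name__)

#: The retained predictor set after multicollinearity screening.
PREDICTORS = [
    "hbct_accuracy",
    "hbct_confidence",
    "cardiac_insight",
    "mean_hr",
    "rmssd",
    "hfnu",
    "pct_satiation_of_max",
    "satiation_t2",
    "fullness_t2",
    "negative_affect_t2",
    "gastric_insight",
    "normo_pct",
]
COVARIATE = "sex"
OUTCOMES = ["debq_emotional", "debq_external", "debq_restrained"]

#: Theoretical instrument bounds used for POMP scoring.
POMP_BOUNDS = {
    "hbct_accuracy": (0.0, 1.0),
    "hbct_confidence": (0.0, 8.0),
    "satiation_rating": (1.0, 7.0),
    "percentage": (0.0, 100.0),
}

#: Variables that are near-deterministic functions of each other, grouped by
#: interoceptive dimension, with the designated variable of interest first.
DEFAULT_DIMENSION_MAP = {
    "wlt_volumes": {
        "retain": "pct_satiation_of_max",
        "members": [
            "pct_satiation_of_max",
            "satiation_volume_ml",
            "additional_volume_ml",
            "total_volume_ml",
        ],
    },
    "egg_bands": {
        "retain": "normo_pct",
        "members": ["normo_pct", "brady_pct", "tachy_pct"],
    },
}

# DEBQ item membership: 30 items, 10 per subscale.
DEBQ_SUBSCALES = {
    "emotional": list(range(0, 10)),
    "external": list(range(10, 20)),
    "restrained": list(range(20, 30)),
}

__all__ = [
    "POMPScore",
    "InsightScore",
    "ScreeningResult",
    "pomp",
    "insight_score",
    "gastric_insight",
    "bmi",
    "debq_scores",
    "assemble_feature_table",
    "vif_screen",
    "PREDICTORS",
    "COVARIATE",
    "OUTCOMES",
    "POMP_BOUNDS",
    "DEFAULT_DIMENSION_MAP",
]


@dataclass
class POMPScore:
    value: float  # 0–100
    source_min: float
    source_max: float


@dataclass
class InsightScore:
    value: float  # 0–100
    accuracy_pomp: POMPScore
    selfreport_pomp: POMPScore


@dataclass
class ScreeningResult:
    vif: dict  # predictor -> VIF at entry (inf for aliased)
    excluded: list = field(default_factory=list)  # (predictor, reason)
    retained: list = field(default_factory=list)


def pomp(x: float, scale_min: float, scale_max: float) -> POMPScore:
    """Percent-Of-Maximum-Possible rescaling of ``x`` onto 0–100."""
    if scale_max <= scale_min:
        raise InvalidParameterError("scale_max must exceed scale_min")
    if not (scale_min <= x <= scale_max):
        raise InvalidParameterError(
            f"value {x} outside instrument bounds [{scale_min}, {scale_max}]"
        )
    value = (x - scale_min) / (scale_max - scale_min) * 100.0
    return POMPScore(value=float(value), source_min=scale_min, source_max=scale_max)


def insight_score(accuracy_pomp: POMPScore, selfreport_pomp: POMPScore) -> InsightScore:
    """100 minus the absolute POMP difference; symmetric in its arguments."""
    value = 100.0 - abs(selfreport_pomp.value - accuracy_pomp.value)
    return InsightScore(
        value=float(value),
        accuracy_pomp=accuracy_pomp,
        selfreport_pomp=selfreport_pomp,
    )


def gastric_insight(indices: WLTIndices, satiation_rating: float) -> InsightScore:
    """Gastric insight from the WLT percentage index and a satiation rating.

    The percentage of satiation to maximum fullness (already 0–100) is the
    objective side; the 1–7 satiation rating is the self-report side.  By
    default the pipeline feeds the rating taken after the first drinking
    phase (t1), the phase the satiation volume refers to.
    """
    if not (1 <= satiation_rating <= 7):
        raise InvalidRatingError(
            f"satiation rating {satiation_rating} outside 1–7"
        )
    pct = indices.pct_satiation_of_max
    acc = pomp(pct, *POMP_BOUNDS["percentage"])
    rep = pomp(satiation_rating, *POMP_BOUNDS["satiation_rating"])
    return insight_score(acc, rep)


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, kg/m²."""
    if weight_kg <= 0 or height_m <= 0:
        raise InvalidParameterError("weight and height must be positive")
    return weight_kg / height_m**2


def debq_scores(item_responses, min_items: int = 8):
    """DEBQ subscale means (emotional, external, restrained), each in [1, 5].

    ``item_responses`` is a length-30 sequence in fixed item order (items
    1–10 emotional, 11–20 external, 21–30 restrained); missing responses may
    be NaN/None.  A subscale mean is computed when at least ``min_items`` of
    its 10 items are present, otherwise it is NaN.
    """
    items = np.array(
        [np.nan if v is None else float(v) for v in item_responses], dtype=float
    )
    if items.size != 30:
        raise InvalidParameterError(f"DEBQ has 30 items, got {items.size}")
    present = items[~np.isnan(items)]
    if np.any((present < 1) | (present > 5)) or np.any(present != np.round(present)):
        raise InvalidRatingError("DEBQ items must be integers in 1–5")

    out = []
    for name in ("emotional", "external", "restrained"):
        sub = items[DEBQ_SUBSCALES[name]]
        n_present = int(np.sum(~np.isnan(sub)))
        out.append(float(np.nanmean(sub)) if n_present >= min_items else np.nan)
    return tuple(out)


def assemble_feature_table(
    features: pd.DataFrame, required_columns=None
) -> pd.DataFrame:
    """Complete-case feature table for the regression stage.

    Takes one row per participant with the 12 retained predictors, the sex
    covariate and the three DEBQ outcomes (extra columns such as ``bmi`` are
    carried through), applies listwise deletion, and logs how many rows were
    dropped.  The dropped count is also stored in ``df.attrs['n_dropped']``.
    """
    if required_columns is None:
        required_columns = PREDICTORS + [COVARIATE] + OUTCOMES
    missing_cols = [c for c in required_columns if c not in features.columns]
    if missing_cols:
        raise InvalidParameterError(f"feature table lacks columns: {missing_cols}")

    complete = features.dropna(subset=required_columns)
    n_dropped = len(features) - len(complete)
    if len(complete) == 0:
        raise InsufficientDataError("no complete cases after listwise deletion")
    if n_dropped:
        logger.info(
            "listwise deletion: dropped %d of %d participants", n_dropped, len(features)
        )
    complete = complete.copy()
    complete.attrs["n_dropped"] = n_dropped
    return complete


def _vif_all(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1-R²_j) from regressing column j on the other columns."""
    n, p = X.shape
    vifs = np.empty(p)
    ones = np.ones((n, 1))
    for j in range(p):
        y = X[:, j]
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            vifs[j] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_screen(
    table: pd.DataFrame,
    predictors=None,
    threshold: float = 10.0,
    dimension_map=None,
) -> ScreeningResult:
    """Exclude collinear predictors by variance inflation factor.

    Exactly aliased columns are dropped first.  Then, while any VIF exceeds
    ``threshold``, the offending predictors are removed: within a dimension
    group of ``dimension_map`` the designated variable of interest is kept
    and the other group members are dropped; a high-VIF predictor outside
    any group is dropped (highest first, VIFs recomputed after each drop).
    Designated variables of interest are never dropped.
    """
    if predictors is None:
        predictors = [c for c in table.columns if c not in OUTCOMES]
    predictors = list(predictors)
    if len(predictors) < 2:
        raise InvalidParameterError("screening needs at least two predictors")
    if len(table) <= len(predictors):
        raise InvalidParameterError("need more rows than predictors for VIF")
    if dimension_map is None:
        dimension_map = DEFAULT_DIMENSION_MAP

    protected = {d["retain"] for d in dimension_map.values()}
    group_of = {
        m: name
        for name, d in dimension_map.items()
        for m in d["members"]
        if m != d["retain"]
    }

    current = list(predictors)
    entry_vif = dict(
        zip(current, _vif_all(table[current].to_numpy(dtype=float)))
    )
    excluded: list = []

    while True:
        vifs = dict(zip(current, _vif_all(table[current].to_numpy(dtype=float))))
        high = {n: v for n, v in vifs.items() if np.isinf(v) or v > threshold}
        droppable = [n for n in high if n not in protected]
        if not droppable:
            if high:
                raise AliasingError(
                    "screening cannot resolve collinearity among designated "
                    f"variables: {sorted(high)}",
                    columns=sorted(high),
                )
            break
        # pick the worst offender; if it belongs to a dimension group, drop
        # every over-threshold non-designated member of that group at once
        # (only the designated variable of interest survives the dimension)
        worst = max(droppable, key=lambda n: vifs[n])
        if worst in group_of:
            dim = group_of[worst]
            batch = [n for n in droppable if group_of.get(n) == dim]
        else:
            batch = [worst]
        for name in batch:
            reason = "aliased" if np.isinf(vifs[name]) else f"vif>{threshold:g}"
            if name in group_of:
                reason += (
                    f" ({group_of[name]} dimension; variable of interest retained)"
                )
            excluded.append((name, reason))
            current.remove(name)
        if len(current) < 2:
            break

    return ScreeningResult(vif=entry_vif, excluded=excluded, retained=current)
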