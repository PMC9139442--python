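"""Tumor-growth response metrics for xenograft (PDX) experiments.

The response of a mouse to treatment is summarized by the normalized tumor
response (NTR): the minimum tumor volume observed at or after the first
drug injection divided by the volume at the injection itself. NTR lies in
(0, 1]; a tumor that never shrinks below its injection-day volume has
NTR = 1, and smaller values mean deeper regression. Per-model medians of
NTR are correlated (Spearman) against transcriptomic efficacy scores; an
informative efficacy signature is anti-correlated with NTR, since high
predicted sensitivity should coincide with strong shrinkage.

Orientation note: the ratio can equivalently be reported as
injection/minimum (>= 1, larger = better response); ``reciprocal=True``
gives that convention. The default keeps larger NTR = worse response so
that score-vs-NTR correlations are negative for a working signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import spearman_rho

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthCurve",
    "ModelResponseSummary",
    "normalized_tumor_response",
    "summarize_model_response",
    "correlate_scores_with_response",
    "growth_curves_to_frame",
    "growth_curves_from_frame",
]


@dataclass
class GrowthCurve:
    """Tumor-volume time series for one mouse."""

    mouse_id: str
    model_id: str
    arm: str  # "control" or "treated"
    days: np.ndarray
    volumes_mm3: np.ndarray
    first_injection_day: float

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.volumes_mm3 = np.asarray(self.volumes_mm3, dtype=float)
        if self.days.shape != self.volumes_mm3.shape or self.days.ndim != 1:
            raise ValueError("days and volumes must be 1-D and aligned")
        if np.any(np.diff(self.days) < 0):
            raise ValueError("days must be non-decreasing")
        if np.any(self.volumes_mm3 <= 0):
            raise ValueError("volumes must be strictly positive")
        if not np.any(self.days >= self.first_injection_day):
            raise ValueError("no measurement at or after first injection")


@dataclass
class ModelResponseSummary:
    """Per-PDX-model response: per-mouse NTRs, their median, efficacy score."""

    model_id: str
    ntr_values: list[float]
    efficacy_score: float
    median_ntr: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.ntr_values:
            raise ValueError("at least one mouse required per model")
        self.median_ntr = float(np.median(self.ntr_values))


def normalized_tumor_response(curve: GrowthCurve, reciprocal: bool = False) -> float:
    """NTR = V_min / V_inj over time points at or after the first injection.

    If no measurement falls exactly on the injection day, the nearest prior
    measurement is used as V_inj (with a warning). ``reciprocal=True``
    returns V_inj / V_min instead.
    """
    at_injection = curve.days == curve.first_injection_day
    if at_injection.any():
        v_inj = float(curve.volumes_mm3[at_injection][0])
    else:
        prior = curve.days < curve.first_injection_day
        if not prior.any():
            raise ValueError(
                f"mouse {curve.mouse_id}: no measurement at or before injection day")
        v_inj = float(curve.volumes_mm3[prior][-1])
        logger.warning("mouse %s: no measurement on injection day %g; "
                       "using nearest prior measurement", curve.mouse_id,
                       curve.first_injection_day)
    post = curve.days >= curve.first_injection_day
    v_min = float(np.min(np.concatenate([curve.volumes_mm3[post], [v_inj]])))
    ntr = v_min / v_inj
    return 1.0 / ntr if reciprocal else ntr


def summarize_model_response(curves: Sequence[GrowthCurve], efficacy_score: float,
                             arm: str | None = "treated") -> ModelResponseSummary:
    """Median NTR of one model's mice (treated arm by default)."""
    selected = [c for c in curves if arm is None or c.arm == arm]
    if not selected:
        raise ValueError("no curves in requested arm")
    model_ids = {c.model_id for c in selected}
    if len(model_ids) != 1:
        raise ValueError(f"curves span multiple models: {sorted(model_ids)}")
    ntrs = [normalized_tumor_response(c) for c in selected]
    return ModelResponseSummary(model_id=model_ids.pop(), ntr_values=ntrs,
                                efficacy_score=efficacy_score)


def correlate_scores_with_response(summaries: Sequence[ModelResponseSummary]) -> float:
    """Spearman rho between per-model efficacy scores and median NTR.

    Negative values indicate that higher predicted sensitivity tracks
    deeper tumor regression. NaN is returned when either vector is
    constant (correlation undefined).
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 models to correlate")
    scores = np.array([s.efficacy_score for s in summaries], dtype=float)
    ntrs = np.array([s.median_ntr for s in summaries], dtype=float)
    return spearman_rho(scores, ntrs)


def growth_curves_to_frame(curves: Sequence[GrowthCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for d, v in zip(c.days, c.volumes_mm3):
            rows.append({"mouse_id": c.mouse_id, "model_id": c.model_id,
                         "arm": c.arm, "day": d, "volume_mm3": v,
                         "first_injection_day": c.first_injection_day})
    return pd.DataFrame(rows)


def growth_curves_from_frame(df: pd.DataFrame) -> list[GrowthCurve]:
    curves = []
    for mouse_id, grp in df.groupby("mouse_id", sort=False):
        grp = grp.sort_values("day")
        curves.append(GrowthCurve(
            mouse_id=str(mouse_id),
            model_id=str(grp["model_id"].iloc[0]),
            arm=str(grp["arm"].iloc[0]),
            days=grp["day"].to_numpy(),
            volumes_mm3=grp["volume_mm3"].to_numpy(),
            first_injection_day=float(grp["first_injection_day"].iloc[0]),
        ))
    return curves
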