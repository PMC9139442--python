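"""Rank-based single-sample scoring of bidirectional gene signatures.

``singscore`` ranks all genes of one sample's expression profile
(ascending, average ranks for ties) and summarizes where the signature
genes sit in that ranking. For an up-set of size m in a profile of n
genes, the mean rank of the set is normalized by its theoretical extremes
— r_min = (m+1)/2 when the set occupies the bottom of the ranking and
r_max = (2n − m + 1)/2 when it occupies the top — and centered by
subtracting 0.5, giving a score in [−0.5, 0.5]. The down-set is scored
identically on reversed ranks (n − rank + 1), so that lowly expressed
down-genes score high. The total score is the sum of the two components
and lies in [−1, 1]. Because only within-sample ranks enter, the score is
invariant under any strictly increasing transform of the profile.

``stingscore`` replaces the whole-transcriptome ranking with the position
of each signature gene relative to a small panel of stably expressed
anchor genes: p(g) = (#anchors below g + 0.5·#anchors tied with g) /
panel size. The up component is mean p over up-genes − 0.5, the down
component 0.5 − mean p over down-genes. Anchoring makes scores comparable
across datasets whose background gene distributions differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .signatures import DrugEfficacySignature

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreResult",
    "StableGenePanel",
    "singscore",
    "stingscore",
    "score_matrix",
]


@dataclass
class ScoreResult:
    """Per-sample signature score and its directional components."""

    sample_id: str
    total_score: float
    up_score: float | None
    down_score: float | None
    n_up_used: int
    n_down_used: int


@dataclass
class StableGenePanel:
    """Anchor genes with near-invariant expression across samples/datasets."""

    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("stable-gene panel must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in stable panel")

    def check_disjoint(self, signature: DrugEfficacySignature) -> None:
        overlap = set(self.genes) & signature.all_genes
        if overlap:
            raise ValueError(
                f"stable panel overlaps signature genes: {sorted(overlap)}")


def _directional_score(mean_rank: float, m: int, n: int) -> float:
    r_min = (m + 1) / 2
    r_max = (2 * n - m + 1) / 2
    return (mean_rank - r_min) / (r_max - r_min) - 0.5


def _present_genes(gene_set: Sequence[str], profile: pd.Series,
                   label: str, sample_id: str) -> list[str]:
    present = [g for g in gene_set if g in profile.index]
    dropped = len(gene_set) - len(present)
    if dropped:
        logger.debug("sample %s: %d %s-set genes absent from profile",
                     sample_id, dropped, label)
    return present


def singscore(profile: pd.Series, signature: DrugEfficacySignature,
              sample_id: str = "sample") -> ScoreResult:
    """Score one expression profile against an up/down signature.

    ``profile`` maps gene id -> expression for a single sample. Signature
    genes absent from the profile are dropped (the number used is
    reported); scoring fails if no signature gene is present.
    """
    if len(profile) < 2:
        raise ValueError("profile must contain at least 2 genes")
    up = _present_genes(signature.up_genes, profile, "up", sample_id)
    down = _present_genes(signature.down_genes, profile, "down", sample_id)
    if not up and not down:
        raise ValueError(f"sample {sample_id}: no signature genes in profile")

    n = len(profile)
    ranks = pd.Series(rankdata(profile.to_numpy(dtype=float)), index=profile.index)

    up_score = down_score = None
    if up:
        up_score = _directional_score(float(ranks[up].mean()), len(up), n)
    if down:
        rev = n - ranks[down] + 1
        down_score = _directional_score(float(rev.mean()), len(down), n)
    total = (up_score or 0.0) + (down_score or 0.0)
    return ScoreResult(sample_id=sample_id, total_score=total,
                       up_score=up_score, down_score=down_score,
                       n_up_used=len(up), n_down_used=len(down))


def _anchor_percentile(value: float, anchors: np.ndarray) -> float:
    below = float(np.sum(anchors < value))
    ties = float(np.sum(anchors == value))
    return (below + 0.5 * ties) / len(anchors)


def stingscore(profile: pd.Series, signature: DrugEfficacySignature,
               panel: StableGenePanel, sample_id: str = "sample") -> ScoreResult:
    """Score a profile against the signature using stable-gene anchors.

    Every panel gene must be present in the profile — the anchors define
    the scale. Signature genes absent from the profile are dropped.
    """
    missing = [g for g in panel.genes if g not in profile.index]
    if missing:
        raise ValueError(f"sample {sample_id}: anchor genes missing from "
                         f"profile: {missing}")
    up = _present_genes(signature.up_genes, profile, "up", sample_id)
    down = _present_genes(signature.down_genes, profile, "down", sample_id)
    if not up and not down:
        raise ValueError(f"sample {sample_id}: no signature genes in profile")

    anchors = profile[panel.genes].to_numpy(dtype=float)
    up_score = down_score = None
    if up:
        p = [_anchor_percentile(float(profile[g]), anchors) for g in up]
        up_score = float(np.mean(p)) - 0.5
    if down:
        p = [_anchor_percentile(float(profile[g]), anchors) for g in down]
        down_score = 0.5 - float(np.mean(p))
    total = (up_score or 0.0) + (down_score or 0.0)
    return ScoreResult(sample_id=sample_id, total_score=total,
                       up_score=up_score, down_score=down_score,
                       n_up_used=len(up), n_down_used=len(down))


def score_matrix(expr: pd.DataFrame, signature: DrugEfficacySignature,
                 method: str = "singscore",
                 panel: StableGenePanel | None = None) -> pd.DataFrame:
    """Score every sample (column) of an expression matrix.

    Returns a DataFrame indexed by sample id with columns ``total_score``,
    ``up_score``, ``down_score``, ``n_up_used`` and ``n_down_used``;
    column order follows the input. Per-sample failures are re-raised with
    the offending sample id attached.
    """
    if method not in ("singscore", "stingscore"):
        raise ValueError(f"unknown scoring method {method!r}")
    if method == "stingscore":
        if panel is None:
            raise ValueError("stingscore requires a stable-gene panel")
        panel.check_disjoint(signature)
    rows = []
    for sample_id in expr.columns:
        profile = expr[sample_id]
        try:
            if method == "singscore":
                res = singscore(profile, signature, sample_id=str(sample_id))
            else:
                res = stingscore(profile, signature, panel, sample_id=str(sample_id))
        except ValueError as exc:
            raise ValueError(f"scoring failed for sample {sample_id!r}: {exc}") from exc
        rows.append({"sample_id": res.sample_id, "total_score": res.total_score,
                     "up_score": res.up_score, "down_score": res.down_score,
                     "n_up_used": res.n_up_used, "n_down_used": res.n_down_used})
    return pd.DataFrame(rows).set_index("sample_id")
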