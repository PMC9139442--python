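"""Agreement metrics, confidence tiers and drug-similarity structure.

Predicted-vs-observed agreement is judged by rank statistics — Spearman's
rho and the concordance index (CI) — because absolute response magnitudes
shift between screening datasets while sample orderings are preserved.
Per-drug prediction models are sorted into confidence tiers from their
per-dataset rho/CI values:

* high   — rho >= 0.4 or CI >= 0.65 in at least one test dataset,
* low    — rho < 0.3 and (CI absent or CI < 0.6) in every test dataset,
* medium — everything else.

Drug-to-drug structure is summarized two ways: Spearman correlation of the
drugs' AUC profiles over shared samples (with a two-sided significance
flag at p = 0.05), and the Jaccard index of their signature gene sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DatasetEvaluation",
    "ConfidenceCall",
    "spearman_rho",
    "spearman_test",
    "concordance_index",
    "evaluate_predictions",
    "classify_confidence",
    "jaccard_index",
    "drug_similarity",
    "stratify_by_score",
    "load_reference_validation_table",
    "classify_reference_table",
]

#: Published per-dataset rank correlations (signature score vs observed
#: response) for the 28 breast-cancer drugs whose prediction models reached
#: medium-or-better confidence; shipped as a worked-example fixture.
_REFERENCE_TSV = "validation_rho_reference.tsv"

#: Dataset columns of the reference table that are independent test sets
#: (the GRAY column is the training screen and takes no part in tiering).
REFERENCE_TEST_DATASETS = ["CCLE", "CTRPv2", "FIMM", "gCSI", "GDSC1000", "Caldas"]


@dataclass
class DatasetEvaluation:
    """Agreement between predicted and observed response on one dataset."""

    drug_id: str
    dataset_id: str
    spearman_rho: float
    concordance_index: float | None = None
    rmse: float | None = None
    mae: float | None = None
    n_samples: int | None = None


@dataclass
class ConfidenceCall:
    drug_id: str
    tier: str  # "high" | "medium" | "low"
    evaluations: list[DatasetEvaluation]


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN when either vector is constant (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


@lru_cache(maxsize=8)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def spearman_test(x: Sequence[float], y: Sequence[float],
                  exact_below: int = 10) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Uses the large-sample t approximation for n >= ``exact_below`` and an
    exact permutation null (all n! orderings of y) below it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = spearman_rho(x, y)
    if np.isnan(rho):
        return rho, float("nan")
    n = len(x)
    if n >= exact_below:
        return rho, float(stats.spearmanr(x, y).pvalue)
    rx = stats.rankdata(x) - (n + 1) / 2
    ry = stats.rankdata(y) - (n + 1) / 2
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    perms = _all_permutations(n)
    null = (ry[perms] @ rx) / denom
    p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    return rho, p


def concordance_index(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Fraction of informative sample pairs ordered concordantly.

    Pairs whose observed values are tied are excluded; pairs with tied
    predictions among the remaining ones score 0.5. Returns NaN when all
    observed values are tied (no informative pairs).
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or len(p) < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    i, j = np.triu_indices(len(p), k=1)
    do = o[i] - o[j]
    informative = do != 0
    if not informative.any():
        return float("nan")
    dp = (p[i] - p[j])[informative]
    do = do[informative]
    score = np.where(dp == 0, 0.5, (np.sign(dp) == np.sign(do)).astype(float))
    return float(score.mean())


def evaluate_predictions(predicted: Sequence[float], observed: Sequence[float],
                         drug_id: str, dataset_id: str) -> DatasetEvaluation:
    """Bundle rho, CI, RMSE and MAE for one (drug, dataset) comparison."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    resid = p - o
    return DatasetEvaluation(
        drug_id=drug_id,
        dataset_id=dataset_id,
        spearman_rho=spearman_rho(p, o),
        concordance_index=concordance_index(p, o),
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        mae=float(np.mean(np.abs(resid))),
        n_samples=len(p),
    )


def classify_confidence(evaluations: Sequence[DatasetEvaluation],
                        high_rho: float = 0.4, high_ci: float = 0.65,
                        low_rho: float = 0.3, low_ci: float = 0.6) -> ConfidenceCall:
    """Assign a high/medium/low confidence tier from per-dataset metrics.

    An undefined (NaN) rho never satisfies the high rule and counts as
    failing the low thresholds, mirroring an absent measurement.
    """
    if not evaluations:
        raise ValueError("at least one dataset evaluation required")
    drug_ids = {e.drug_id for e in evaluations}
    if len(drug_ids) != 1:
        raise ValueError(f"evaluations span multiple drugs: {sorted(drug_ids)}")

    def _ge(value, threshold):
        return value is not None and not np.isnan(value) and value >= threshold

    high = any(_ge(e.spearman_rho, high_rho) or _ge(e.concordance_index, high_ci)
               for e in evaluations)
    if high:
        tier = "high"
    else:
        low = all(not _ge(e.spearman_rho, low_rho)
                  and not _ge(e.concordance_index, low_ci)
                  for e in evaluations)
        tier = "low" if low else "medium"
    return ConfidenceCall(drug_id=drug_ids.pop(), tier=tier,
                          evaluations=list(evaluations))


def jaccard_index(a: set, b: set) -> float:
    """|A ∩ B| / |A ∪ B|; by convention 1.0 for two empty sets."""
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def drug_similarity(auc_table: pd.DataFrame, signatures: Sequence,
                    alpha: float = 0.05, separate_tails: bool = False,
                    min_pairwise: int = 3):
    """Response- and signature-level similarity between drugs.

    Parameters
    ----------
    auc_table : pd.DataFrame
        Samples x drugs AUC values; NaN marks unscreened combinations.
    signatures : sequence of DrugEfficacySignature
        One per drug; gene sets compared via the Jaccard index over the
        union of up and down genes (or per tail if ``separate_tails``).
    alpha : float
        Two-sided significance level for the response-correlation flag.

    Returns
    -------
    response_sim, response_significant, signature_sim : pd.DataFrame
        Square symmetric matrices indexed by drug. Pairs with fewer than
        ``min_pairwise`` shared samples get NaN response similarity. With
        ``separate_tails`` the third element is a dict with keys
        ``"up"`` and ``"down"``.
    """
    drugs = list(auc_table.columns)
    if len(drugs) < 2:
        raise ValueError("need at least two drugs")
    n = len(drugs)
    rho_m = pd.DataFrame(np.eye(n), index=drugs, columns=drugs)
    sig_flag = pd.DataFrame(np.eye(n, dtype=bool), index=drugs, columns=drugs)
    for a, b in itertools.combinations(drugs, 2):
        pair = auc_table[[a, b]].dropna()
        if len(pair) < min_pairwise:
            rho_m.loc[a, b] = rho_m.loc[b, a] = np.nan
            sig_flag.loc[a, b] = sig_flag.loc[b, a] = False
            continue
        rho, p = spearman_test(pair[a].to_numpy(), pair[b].to_numpy())
        rho_m.loc[a, b] = rho_m.loc[b, a] = rho
        flag = bool(p <= alpha) if not np.isnan(p) else False
        sig_flag.loc[a, b] = sig_flag.loc[b, a] = flag

    by_drug = {s.drug_id: s for s in signatures}
    missing = [d for d in drugs if d not in by_drug]
    if missing:
        raise ValueError(f"signatures missing for drugs: {missing}")

    def _jaccard_matrix(getter) -> pd.DataFrame:
        m = pd.DataFrame(np.eye(n), index=drugs, columns=drugs)
        for a, b in itertools.combinations(drugs, 2):
            j = jaccard_index(getter(by_drug[a]), getter(by_drug[b]))
            m.loc[a, b] = m.loc[b, a] = j
        # a drug compared with itself always matches perfectly
        np.fill_diagonal(m.values, 1.0)
        return m

    if separate_tails:
        sig_sim = {"up": _jaccard_matrix(lambda s: set(s.up_genes)),
                   "down": _jaccard_matrix(lambda s: set(s.down_genes))}
    else:
        sig_sim = _jaccard_matrix(lambda s: set(s.up_genes) | set(s.down_genes))
    return rho_m, sig_flag, sig_sim


def stratify_by_score(scores: pd.Series, lower_q: float = 0.10,
                      upper_q: float = 0.90) -> pd.Series:
    """Tag samples as bottom / middle / top by score quantile.

    Bottom: score <= the ``lower_q`` quantile; top: score >= the
    ``upper_q`` quantile; quantiles use linear interpolation. A constant
    score vector puts every sample in the bottom tier (warning logged).
    """
    scores = pd.Series(scores, dtype=float)
    lo = float(np.quantile(scores.to_numpy(), lower_q))
    hi = float(np.quantile(scores.to_numpy(), upper_q))
    if lo == hi:
        logger.warning("degenerate score distribution: all samples in one tier")
    tiers = pd.Series("middle", index=scores.index, name="tier")
    tiers[scores >= hi] = "top"
    tiers[scores <= lo] = "bottom"  # bottom wins when both apply (degenerate)
    return tiers


def load_reference_validation_table() -> pd.DataFrame:
    """Load the packaged published validation-correlation table.

    Wide format: one row per drug; columns are the training screen (GRAY),
    six test datasets, and the published confidence label. Missing entries
    (drug not screened in that dataset) are NaN.
    """
    with resources.files("drugsig.data").joinpath(_REFERENCE_TSV).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


def classify_reference_table(table: pd.DataFrame | None = None,
                             **thresholds) -> pd.DataFrame:
    """Apply the confidence-tier rule to the packaged reference table.

    Only the independent test-set columns enter the rule (no CI values are
    published, so tiering rests on rho alone). Returns the table with a
    ``computed_confidence`` column alongside the published label.
    """
    if table is None:
        table = load_reference_validation_table()
    out = table.copy()
    tiers = []
    for _, row in out.iterrows():
        evals = [DatasetEvaluation(drug_id=row["drug"], dataset_id=ds,
                                   spearman_rho=float(row[ds]))
                 for ds in REFERENCE_TEST_DATASETS if pd.notna(row[ds])]
        tiers.append(classify_confidence(evals, **thresholds).tier)
    out["computed_confidence"] = tiers
    return out
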