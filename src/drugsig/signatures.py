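"""Resampling-based derivation of drug efficacy gene signatures.

For one drug, the derivation repeatedly draws a fixed fraction of the
cohort (80% of cell lines, 1000 draws by default, without replacement),
computes the Spearman correlation of every gene's log-expression with the
drug-response AUC within the draw, and marks the genes falling in the top
and bottom 3% of the correlation ranking. Genes that land in a tail in at
least 90% of the draws form the signature: the top tail (positive
correlation with AUC, i.e. with sensitivity) becomes the up-regulated set,
the bottom tail the down-regulated set.

Tail membership is by rank, so exactly ``k = max(1, round(tail_fraction *
n_genes))`` genes occupy each tail per draw; boundary ties are broken by
stable input gene order, making the whole derivation deterministic for a
fixed seed and input ordering. Genes with zero expression variance inside
a draw have no defined correlation and are excluded from both tails for
that draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureDerivationParams",
    "DrugEfficacySignature",
    "resample_correlations",
    "derive_signature",
    "signature_to_gmt_sets",
    "signature_from_gmt_sets",
]


@dataclass(frozen=True)
class SignatureDerivationParams:
    """Knobs of the resampling derivation; defaults are the published ones."""

    resample_fraction: float = 0.8
    n_resamples: int = 1000
    tail_fraction: float = 0.03
    min_frequency: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.resample_fraction <= 1:
            raise ValueError("resample_fraction must lie in (0, 1]")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be positive")
        if not 0 < self.tail_fraction < 0.5:
            raise ValueError("tail_fraction must lie in (0, 0.5)")
        if not 0 <= self.min_frequency <= 1:
            raise ValueError("min_frequency must lie in [0, 1]")


@dataclass
class DrugEfficacySignature:
    """Up/down gene sets for one drug with selection bookkeeping.

    ``frequencies`` carries, per gene, the fraction of resampling runs in
    which it fell in the top (``up_frequency``) or bottom
    (``down_frequency``) correlation tail, plus its median Spearman rho.
    """

    drug_id: str
    up_genes: list[str]
    down_genes: list[str]
    frequencies: pd.DataFrame = field(repr=False)
    min_frequency: float = 0.90

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down gene sets must be disjoint")

    @property
    def all_genes(self) -> set[str]:
        return set(self.up_genes) | set(self.down_genes)

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


def _spearman_matrix(expr_values: np.ndarray, auc_values: np.ndarray) -> np.ndarray:
    """Per-row Spearman rho of a genes x samples block against one vector.

    Rows (or a y vector) with zero variance get NaN.
    """
    rx = rankdata(expr_values, axis=1).astype(float)
    ry = rankdata(auc_values).astype(float)
    rx -= rx.mean(axis=1, keepdims=True)
    ry -= ry.mean()
    sx = np.sqrt((rx ** 2).sum(axis=1))
    sy = np.sqrt((ry ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx @ ry) / (sx * sy)
    rho[sx == 0] = np.nan
    if sy == 0:
        rho[:] = np.nan
    return rho


def resample_correlations(expr: pd.DataFrame, auc: pd.Series,
                          params: SignatureDerivationParams,
                          resample_indices: list[np.ndarray] | None = None,
                          ) -> pd.DataFrame:
    """Tail-membership frequencies of every gene across resampling runs.

    Parameters
    ----------
    expr : pd.DataFrame
        Log-expression, genes x samples.
    auc : pd.Series
        Drug response per sample (higher = more sensitive), aligned to
        ``expr.columns``.
    params : SignatureDerivationParams
    resample_indices : list of int arrays, optional
        Explicit positional sample draws, overriding the seeded ones;
        intended for reproducibility harnesses.

    Returns
    -------
    pd.DataFrame indexed by gene with columns ``up_frequency``,
    ``down_frequency``, ``median_rho`` and ``n_valid`` (number of draws
    with a defined correlation).
    """
    auc = auc.reindex(expr.columns)
    if auc.isna().any():
        raise ValueError("AUC missing for some samples in the expression matrix")
    n_samples = expr.shape[1]
    n_genes = expr.shape[0]
    m = int(np.floor(params.resample_fraction * n_samples))
    if m < 5:
        raise ValueError(f"resamples of {m} samples are too small (need >= 5)")
    k = max(1, round(params.tail_fraction * n_genes))

    if resample_indices is None:
        rng = np.random.default_rng(params.seed)
        resample_indices = [rng.choice(n_samples, size=m, replace=False)
                            for _ in range(params.n_resamples)]
    elif len(resample_indices) != params.n_resamples:
        raise ValueError("resample_indices length must equal n_resamples")

    X = expr.to_numpy(dtype=float)
    y = auc.to_numpy(dtype=float)
    top_counts = np.zeros(n_genes)
    bottom_counts = np.zeros(n_genes)
    rho_store = np.empty((params.n_resamples, n_genes), dtype=np.float32)
    n_undefined = 0
    for r, idx in enumerate(resample_indices):
        rho = _spearman_matrix(X[:, idx], y[idx])
        rho_store[r] = rho
        undefined = np.isnan(rho)
        n_undefined += int(undefined.sum())
        # undefined correlations can never occupy a tail
        top_order = np.argsort(np.where(undefined, np.inf, -rho), kind="stable")
        bottom_order = np.argsort(np.where(undefined, np.inf, rho), kind="stable")
        top_counts[top_order[:k]] += 1
        bottom_counts[bottom_order[:k]] += 1
    if n_undefined:
        logger.info("%d gene-resample correlations undefined (zero variance); "
                    "excluded from tails", n_undefined)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="All-NaN slice")
        median_rho = np.nanmedian(rho_store, axis=0)
    return pd.DataFrame({
        "up_frequency": top_counts / params.n_resamples,
        "down_frequency": bottom_counts / params.n_resamples,
        "median_rho": median_rho,
        "n_valid": params.n_resamples - np.isnan(rho_store).sum(axis=0),
    }, index=expr.index)


def derive_signature(frequencies: pd.DataFrame, params: SignatureDerivationParams,
                     drug_id: str = "drug") -> DrugEfficacySignature:
    """Select the up/down gene sets from tail-membership frequencies.

    A gene enters the up (down) set when its top-tail (bottom-tail)
    frequency reaches ``min_frequency``. With degenerate parameters a gene
    could qualify for both tails; it is then assigned to the tail where it
    appeared more often (ties resolved by the sign of its median rho).
    """
    up_mask = frequencies["up_frequency"] >= params.min_frequency
    down_mask = frequencies["down_frequency"] >= params.min_frequency
    both = up_mask & down_mask
    if both.any():
        prefer_up = (frequencies["up_frequency"] > frequencies["down_frequency"]) | (
            (frequencies["up_frequency"] == frequencies["down_frequency"])
            & (frequencies["median_rho"] >= 0))
        up_mask = up_mask & (~both | prefer_up)
        down_mask = down_mask & (~both | ~prefer_up)
    up_genes = list(frequencies.index[up_mask])
    down_genes = list(frequencies.index[down_mask])
    if not up_genes and not down_genes:
        logger.warning("empty signature for drug %s at min_frequency=%g",
                       drug_id, params.min_frequency)
    return DrugEfficacySignature(drug_id=drug_id, up_genes=up_genes,
                                 down_genes=down_genes, frequencies=frequencies,
                                 min_frequency=params.min_frequency)


def signature_to_gmt_sets(sig: DrugEfficacySignature) -> dict[str, list[str]]:
    """Two GMT records per drug: ``<drug>_UP`` and ``<drug>_DN``."""
    return {f"{sig.drug_id}_UP": list(sig.up_genes),
            f"{sig.drug_id}_DN": list(sig.down_genes)}


def signature_from_gmt_sets(sets: dict[str, list[str]], drug_id: str,
                            ) -> DrugEfficacySignature:
    up = sets.get(f"{drug_id}_UP", [])
    down = sets.get(f"{drug_id}_DN", [])
    if not up and not down:
        raise KeyError(f"no GMT records for drug {drug_id!r}")
    freq = pd.DataFrame({"up_frequency": np.nan, "down_frequency": np.nan,
                         "median_rho": np.nan, "n_valid": np.nan},
                        index=pd.Index(list(up) + list(down), name="gene_id"))
    return DrugEfficacySignature(drug_id=drug_id, up_genes=list(up),
                                 down_genes=list(down), frequencies=freq)
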