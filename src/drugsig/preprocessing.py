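"""Turn gene-level read counts into the filtered log-expression matrix.

The pipeline consumes log2(RPKM + offset) expression values from RNA-seq
counts. Lowly expressed genes are removed with an edgeR-style rule: a gene
is kept if its counts-per-million strictly exceed a threshold in at least a
fixed fraction of samples. Library sizes are the column sums of the full
(pre-filter) count matrix and are carried through filtering so that CPM and
RPKM are always computed against the sequencing depth actually observed.

Technical replicates are merged by summing counts, or by taking per-gene
median log-expression, depending on which representation is being merged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "filter_genes_by_cpm",
    "counts_to_log_rpkm",
    "merge_technical_replicates_expression",
    "merge_technical_replicates_counts",
]


@dataclass
class CountMatrix:
    """Genes x samples integer read counts with per-gene lengths.

    Parameters
    ----------
    counts : pd.DataFrame
        Non-negative integer counts, genes in rows, samples in columns.
    gene_lengths : pd.Series
        Transcript length in bp per gene, aligned to ``counts.index``.
    library_sizes : pd.Series, optional
        Per-sample total counts. Defaults to the column sums of ``counts``;
        preserved across gene filtering so depth refers to the full library.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    library_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = self.gene_lengths.index[self.gene_lengths.isna()]
            raise ValueError(f"missing gene lengths for {list(missing[:5])} ...")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be strictly positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts.to_numpy(), np.round(self.counts.to_numpy())):
            raise ValueError("counts must be integral")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns).astype(float)
            if self.library_sizes.isna().any():
                raise ValueError("library_sizes must cover every sample")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def cpm(self) -> pd.DataFrame:
        """Counts per million against the stored library sizes."""
        lib = self.library_sizes
        if (lib <= 0).any():
            bad = lib.index[lib <= 0]
            raise ValueError(f"zero/negative library size for samples {list(bad)}")
        return self.counts.div(lib, axis=1) * 1e6


def filter_genes_by_cpm(counts: CountMatrix, cpm_threshold: float = 2.0,
                        min_fraction: float = 0.10) -> CountMatrix:
    """Keep genes with CPM > ``cpm_threshold`` in >= ``min_fraction`` of samples.

    The comparison against the threshold is strict; the sample-count
    requirement ``ceil(min_fraction * n_samples)`` is inclusive. Library
    sizes of the input are preserved on the returned matrix.
    """
    if cpm_threshold <= 0:
        raise ValueError("cpm_threshold must be positive")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    n_required = math.ceil(min_fraction * counts.counts.shape[1])
    passing = (counts.cpm() > cpm_threshold).sum(axis=1) >= n_required
    if not passing.any():
        logger.warning("CPM filter removed every gene")
    return CountMatrix(
        counts=counts.counts.loc[passing],
        gene_lengths=counts.gene_lengths.loc[passing],
        library_sizes=counts.library_sizes,
    )


def counts_to_log_rpkm(counts: CountMatrix, offset: float = 1.0,
                       log_base: float = 2.0) -> pd.DataFrame:
    """log(RPKM + offset) expression matrix.

    RPKM_gs = count_gs * 1e9 / (library_size_s * length_g). The additive
    offset keeps zero counts finite; with the default offset of 1 a zero
    count maps to exactly 0.
    """
    lib = counts.library_sizes
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    rpkm = counts.counts.mul(1e9, axis=0).div(lib, axis=1).div(
        counts.gene_lengths.astype(float), axis=0)
    return np.log2(rpkm + offset) if log_base == 2.0 else \
        np.log(rpkm + offset) / np.log(log_base)


def _groups(replicate_map: Mapping[str, str], sample_ids) -> dict[str, list[str]]:
    missing = [s for s in sample_ids if s not in replicate_map]
    if missing:
        raise ValueError(f"samples without replicate group: {missing[:5]}")
    groups: dict[str, list[str]] = {}
    for s in sample_ids:
        groups.setdefault(replicate_map[s], []).append(s)
    for g, members in groups.items():
        if not members:
            raise ValueError(f"empty replicate group {g!r}")
    return groups


def merge_technical_replicates_expression(expr: pd.DataFrame,
                                          replicate_map: Mapping[str, str]) -> pd.DataFrame:
    """Collapse technical replicates to their per-gene median log-expression."""
    groups = _groups(replicate_map, expr.columns)
    merged = {g: expr[members].median(axis=1) for g, members in groups.items()}
    return pd.DataFrame(merged)


def merge_technical_replicates_counts(counts: CountMatrix,
                                      replicate_map: Mapping[str, str]) -> CountMatrix:
    """Collapse technical replicates by summing their read counts."""
    groups = _groups(replicate_map, counts.counts.columns)
    merged = pd.DataFrame({g: counts.counts[members].sum(axis=1)
                           for g, members in groups.items()})
    return CountMatrix(counts=merged, gene_lengths=counts.gene_lengths)
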