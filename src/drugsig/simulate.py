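"""Synthetic pharmacogenomic cohorts with planted drug-sensitivity structure.

The generator emulates the statistical skeleton of a cell-line drug
screen: each sample carries a latent drug-sensitivity value s ~ N(0, 1);
the drug-response AUC (activity area, higher = more sensitive) is an
affine function of s plus Gaussian noise, clamped to [0, 1]; a chosen set
of "up" genes gains log-expression ``effect_size * s`` on top of its
baseline, a "down" set loses the same amount, and all remaining genes are
baseline plus noise. Read counts are derived from the log-expression by
inverting the log2(RPKM + 1) transform, converting RPKM to an expected
read count given each sample's library size and each gene's length, and
Poisson sampling — so count preprocessing approximately round-trips to
the simulated expression.

A batch-shifted companion cohort supports cross-dataset scoring tests:
it shares the planted programs and the per-sample latent values (samples
are matched one-to-one) but has independent measurement noise, and its
background genes are distorted by a dataset-level affine shift/scale.
Signature and anchor genes keep their calibration — the regime in which
stable-gene anchoring (stingscore) restores comparability while
whole-transcriptome ranking (singscore) drifts.

Per-mouse tumor growth curves round out the inputs: resistant arms grow
monotonically, responder arms shrink below the injection-day volume
before regrowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import io
from .invivo import GrowthCurve, growth_curves_to_frame
from .preprocessing import CountMatrix

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "Cohort",
    "BatchShiftedPair",
    "generate_cohort",
    "generate_batch_shifted_pair",
    "generate_growth_curves",
    "write_cohort",
]

#: log-scale SD of the designated stably expressed anchor genes
STABLE_GENE_SD = 0.01


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the simulated screen.

    Defaults give a 1000-gene, 60-sample cohort with 20 sensitivity- and
    20 resistance-associated genes at effect size 1.5 against expression
    noise SD 0.3, and AUC = 0.5 + 0.15 s + N(0, 0.05²) clamped to [0, 1].
    """

    n_genes: int = 1000
    n_samples: int = 60
    n_up: int = 20
    n_down: int = 20
    effect_size: float = 1.5
    noise_sd_expr: float = 0.3
    noise_sd_auc: float = 0.05
    auc_intercept: float = 0.5
    auc_slope: float = 0.15
    seed: int = 0
    library_size_range: tuple[int, int] = (2_000_000, 5_000_000)
    gene_length_range: tuple[int, int] = (300, 10_000)
    drug_id: str = "drug_1"
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples) < 1:
            raise ValueError("n_genes and n_samples must be positive")
        if self.n_up < 0 or self.n_down < 0:
            raise ValueError("planted gene counts must be non-negative")
        if self.n_up + self.n_down >= self.n_genes:
            raise ValueError("n_up + n_down must be smaller than n_genes")
        if min(self.noise_sd_expr, self.noise_sd_auc) < 0:
            raise ValueError("noise SDs must be non-negative")
        for lo, hi in (self.library_size_range, self.gene_length_range):
            if lo <= 0 or hi < lo:
                raise ValueError("ranges must be positive with lo <= hi")


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort for recovery checks."""

    planted_up_genes: list[str]
    planted_down_genes: list[str]
    latent_sensitivity: pd.Series
    stable_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.planted_up_genes) & set(self.planted_down_genes):
            raise ValueError("planted up/down sets must be disjoint")


class Cohort(NamedTuple):
    counts: CountMatrix
    expression: pd.DataFrame
    response: pd.DataFrame  # samples x drugs AUC
    truth: TruthRecord


class BatchShiftedPair(NamedTuple):
    expression_a: pd.DataFrame
    expression_b: pd.DataFrame
    stable_genes: list[str]
    truth: TruthRecord


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _plant_structure(rng: np.random.Generator, config: SyntheticConfig,
                     n_reserved: int = 0):
    """Gene ids, baselines, planted index sets shared by paired cohorts."""
    gene_ids = _ids("g", config.n_genes)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    chosen = rng.choice(config.n_genes, size=config.n_up + config.n_down + n_reserved,
                        replace=False)
    up_idx = chosen[:config.n_up]
    down_idx = chosen[config.n_up:config.n_up + config.n_down]
    reserved_idx = chosen[config.n_up + config.n_down:]
    slope = np.zeros(config.n_genes)
    slope[up_idx] = config.effect_size
    slope[down_idx] = -config.effect_size
    return gene_ids, baseline, slope, up_idx, down_idx, reserved_idx


def _expression(rng: np.random.Generator, config: SyntheticConfig,
                baseline: np.ndarray, slope: np.ndarray,
                latent: np.ndarray) -> np.ndarray:
    noise = rng.normal(0.0, config.noise_sd_expr, (config.n_genes, len(latent)))
    return baseline[:, None] + slope[:, None] * latent[None, :] + noise


def _auc(rng: np.random.Generator, config: SyntheticConfig,
         latent: np.ndarray) -> np.ndarray:
    raw = (config.auc_intercept + config.auc_slope * latent
           + rng.normal(0.0, config.noise_sd_auc, len(latent)))
    return np.clip(raw, 0.0, 1.0)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Simulate counts, log-expression, drug response and ground truth.

    Identical configs (including seed) yield bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids, baseline, slope, up_idx, down_idx, _ = _plant_structure(rng, config)
    sample_ids = _ids("s", config.n_samples)

    latent = rng.standard_normal(config.n_samples)
    auc = _auc(rng, config, latent)
    expr_values = _expression(rng, config, baseline, slope, latent)

    gene_lengths = rng.integers(config.gene_length_range[0],
                                config.gene_length_range[1] + 1, config.n_genes)
    lib_sizes = rng.integers(config.library_size_range[0],
                             config.library_size_range[1] + 1, config.n_samples)
    # invert log2(RPKM + 1), then expected reads = RPKM * length * depth / 1e9
    rpkm = np.maximum(np.exp2(expr_values) - 1.0, 0.0)
    expected = rpkm * gene_lengths[:, None] * lib_sizes[None, :] / 1e9
    counts_values = rng.poisson(expected)

    gene_index = pd.Index(gene_ids, name="gene_id")
    expression = pd.DataFrame(expr_values, index=gene_index, columns=sample_ids)
    counts = CountMatrix(
        counts=pd.DataFrame(counts_values, index=gene_index, columns=sample_ids),
        gene_lengths=pd.Series(gene_lengths, index=gene_index, name="length_bp"),
    )
    response = pd.DataFrame({config.drug_id: auc},
                            index=pd.Index(sample_ids, name="sample_id"))
    truth = TruthRecord(
        planted_up_genes=[gene_ids[i] for i in up_idx],
        planted_down_genes=[gene_ids[i] for i in down_idx],
        latent_sensitivity=pd.Series(latent, index=sample_ids, name="latent"),
    )
    return Cohort(counts=counts, expression=expression, response=response,
                  truth=truth)


def generate_batch_shifted_pair(config: SyntheticConfig, shift: float,
                                scale: float, n_stable: int = 5,
                                ) -> BatchShiftedPair:
    """Two cohorts sharing planted programs; the second batch-distorted.

    The cohorts share gene baselines, planted gene sets and per-sample
    latent sensitivity (columns are matched one-to-one) but draw
    independent measurement noise. In the second cohort every background
    (non-signature, non-anchor) gene is transformed x -> shift + scale*x,
    emulating a dataset-level processing difference in the transcriptome
    background. ``n_stable`` designated anchor genes are near-constant
    (log-scale SD 0.01) in both cohorts.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if n_stable < 1:
        raise ValueError("n_stable must be >= 1")
    if n_stable + config.n_up + config.n_down >= config.n_genes:
        raise ValueError("n_stable leaves no background genes")

    rng = np.random.default_rng(config.seed)
    gene_ids, baseline, slope, up_idx, down_idx, stable_idx = _plant_structure(
        rng, config, n_reserved=n_stable)
    latent = rng.standard_normal(config.n_samples)

    def _one(noise_rng: np.random.Generator) -> np.ndarray:
        values = _expression(noise_rng, config, baseline, slope, latent)
        values[stable_idx, :] = (baseline[stable_idx][:, None]
                                 + noise_rng.normal(0.0, STABLE_GENE_SD,
                                                    (n_stable, config.n_samples)))
        return values

    values_a = _one(rng)
    values_b = _one(rng)
    background = np.ones(config.n_genes, dtype=bool)
    background[np.concatenate([up_idx, down_idx, stable_idx])] = False
    values_b[background, :] = shift + scale * values_b[background, :]

    gene_index = pd.Index(gene_ids, name="gene_id")
    samples_a = _ids("a", config.n_samples)
    samples_b = _ids("b", config.n_samples)
    truth = TruthRecord(
        planted_up_genes=[gene_ids[i] for i in up_idx],
        planted_down_genes=[gene_ids[i] for i in down_idx],
        latent_sensitivity=pd.Series(latent, index=samples_a, name="latent"),
        stable_genes=[gene_ids[i] for i in stable_idx],
    )
    return BatchShiftedPair(
        expression_a=pd.DataFrame(values_a, index=gene_index, columns=samples_a),
        expression_b=pd.DataFrame(values_b, index=gene_index, columns=samples_b),
        stable_genes=truth.stable_genes,
        truth=truth,
    )


def generate_growth_curves(n_mice: int, responder: bool, seed: int,
                           model_id: str = "model", arm: str = "treated",
                           first_injection_day: float = 14.0,
                           n_weeks_post: int = 6) -> list[GrowthCurve]:
    """Simulate per-mouse caliper measurements (two per week).

    Treatment starts once tumors reach ~200 mm³ (the injection-day
    volume). Resistant mice grow strictly monotonically; responder mice
    shrink below the injection volume to a nadir and then regrow.
    """
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    rng = np.random.default_rng(seed)
    days = []
    d = 0.0
    while d <= first_injection_day + 7 * n_weeks_post:
        days.append(d)
        d += 3.0 if (len(days) % 2) else 4.0
    days = np.array(days)
    if first_injection_day not in days:
        days = np.sort(np.append(days, first_injection_day))

    curves = []
    for mouse in range(n_mice):
        growth = rng.uniform(0.04, 0.08)
        v_inj = 200.0 * rng.uniform(0.95, 1.05)
        volumes = np.empty_like(days)
        for i, day in enumerate(days):
            if day <= first_injection_day:
                volumes[i] = v_inj * np.exp(growth * (day - first_injection_day))
        post = days > first_injection_day
        if responder:
            decay = rng.uniform(0.08, 0.15)
            nadir_day = first_injection_day + rng.uniform(15.0, 22.0)
            regrow = rng.uniform(0.02, 0.05)
            for i, day in enumerate(days):
                if not post[i]:
                    continue
                if day <= nadir_day:
                    volumes[i] = v_inj * np.exp(-decay * (day - first_injection_day))
                else:
                    nadir_v = v_inj * np.exp(-decay * (nadir_day - first_injection_day))
                    volumes[i] = nadir_v * np.exp(regrow * (day - nadir_day))
        else:
            v = v_inj
            prev_day = first_injection_day
            for i, day in enumerate(days):
                if not post[i]:
                    continue
                # strictly positive multiplicative increments: monotone growth
                v *= np.exp(growth * (day - prev_day) * rng.uniform(0.5, 1.5))
                volumes[i] = v
                prev_day = day
        curves.append(GrowthCurve(
            mouse_id=f"{model_id}_m{mouse + 1}", model_id=model_id, arm=arm,
            days=days.copy(), volumes_mm3=volumes,
            first_injection_day=first_injection_day))
    return curves


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort to TSV/JSON files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "gene_lengths": out / "gene_lengths.tsv",
        "expression": out / "expression.tsv",
        "response": out / "response_auc.tsv",
        "truth": out / "truth.json",
    }
    io.write_matrix_tsv(cohort.counts.counts, paths["counts"])
    io.write_gene_lengths_tsv(cohort.counts.gene_lengths, paths["gene_lengths"])
    io.write_matrix_tsv(cohort.expression, paths["expression"])
    io.write_auc_tsv(cohort.response, paths["response"])
    io.write_json({
        "planted_up_genes": cohort.truth.planted_up_genes,
        "planted_down_genes": cohort.truth.planted_down_genes,
        "latent_sensitivity": cohort.truth.latent_sensitivity.round(10).to_dict(),
    }, paths["truth"])
    return paths


def write_growth_curves(curves: list[GrowthCurve], path: str | Path) -> None:
    io.write_growth_curves_csv(growth_curves_to_frame(curves), path)
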