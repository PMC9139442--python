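"""End-to-end orchestration: derive -> score -> train -> evaluate -> classify.

The stages are thin compositions of the library modules, driven by a
single :class:`PipelineConfig` and a single global seed fanned out to
stage- and drug-specific child seeds, so that any stage can be re-run
independently and reproducibly. All file outputs are plain text (TSV,
GMT, JSON).
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io
from .evaluation import (DatasetEvaluation, classify_confidence,
                         evaluate_predictions)
from .models import ALL_METHODS, CVReport, cross_validate
from .scoring import StableGenePanel, score_matrix
from .signatures import (DrugEfficacySignature, SignatureDerivationParams,
                         derive_signature, resample_correlations,
                         signature_to_gmt_sets)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "child_seed",
    "run_derivation",
    "run_training",
    "run_validation",
]


def child_seed(seed: int, *keys: int | str) -> int:
    """Deterministic stage/drug-specific child seed below 2**31."""
    entropy = [seed] + [zlib.crc32(k.encode()) if isinstance(k, str) else int(k)
                        for k in keys]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """All knobs of the pipeline in one place.

    Numeric defaults: derivation parameters per
    :class:`SignatureDerivationParams`; confidence thresholds rho 0.4 /
    CI 0.65 (high) and rho 0.3 / CI 0.6 (low).
    """

    expression_tsv: str | None = None
    response_tsv: str | None = None
    derivation: SignatureDerivationParams = field(
        default_factory=SignatureDerivationParams)
    scoring_method: str = "singscore"
    stable_genes: list[str] = field(default_factory=list)
    methods: list[str] = field(default_factory=lambda: list(ALL_METHODS))
    cv_k: int = 3
    cv_repeats: int = 20
    high_rho: float = 0.4
    high_ci: float = 0.65
    low_rho: float = 0.3
    low_ci: float = 0.6
    drop_overlap: bool = False
    seed: int = 0
    out_dir: str = "drugsig_out"

    def __post_init__(self) -> None:
        for t in (self.high_rho, self.high_ci, self.low_rho, self.low_ci):
            if not 0 <= t <= 1:
                raise ValueError("confidence thresholds must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        deriv = raw.pop("derivation", {})
        cfg = cls(**raw)
        if deriv:
            cfg.derivation = SignatureDerivationParams(**deriv)
        return cfg

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["derivation"] = asdict(self.derivation)
        return d

    def panel(self) -> StableGenePanel | None:
        return StableGenePanel(list(self.stable_genes)) if self.stable_genes else None


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            logger.info("stage %s: done in %.2fs", name,
                        time.perf_counter() - self.t0)
            return False
    return _Timer()


def run_derivation(config: PipelineConfig, expression: pd.DataFrame,
                   response: pd.DataFrame, out_dir: str | Path | None = None,
                   ) -> tuple[dict[str, DrugEfficacySignature], dict]:
    """Derive one signature per drug column of ``response``.

    Samples without an AUC for a given drug are dropped for that drug;
    drug columns with fewer than 7 usable samples are skipped with a
    warning (below that the 80% draws fall under the 5-sample floor).
    Writes ``signatures.gmt``, a long-format ``frequencies.tsv`` and a
    ``derivation_manifest.json`` when ``out_dir`` is given.
    """
    signatures: dict[str, DrugEfficacySignature] = {}
    freq_frames = []
    with _stage("derive"):
        for j, drug in enumerate(response.columns):
            auc = response[drug].dropna()
            shared = expression.columns.intersection(auc.index)
            if len(shared) < 7:
                logger.warning("drug %s: only %d usable samples; skipped",
                               drug, len(shared))
                continue
            params = SignatureDerivationParams(
                resample_fraction=config.derivation.resample_fraction,
                n_resamples=config.derivation.n_resamples,
                tail_fraction=config.derivation.tail_fraction,
                min_frequency=config.derivation.min_frequency,
                seed=child_seed(config.seed, "derive", j))
            freq = resample_correlations(expression[shared], auc[shared], params)
            signatures[drug] = derive_signature(freq, params, drug_id=drug)
            freq_frames.append(freq.assign(drug=drug))
    manifest = {
        "parameters": config.to_manifest(),
        "n_resamples": config.derivation.n_resamples,
        "drugs": {d: {"n_up": len(s.up_genes), "n_down": len(s.down_genes)}
                  for d, s in signatures.items()},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gmt_sets: dict[str, list[str]] = {}
        for s in signatures.values():
            gmt_sets.update(signature_to_gmt_sets(s))
        io.write_gmt(gmt_sets, out / "signatures.gmt")
        if freq_frames:
            pd.concat(freq_frames).to_csv(out / "frequencies.tsv", sep="\t")
        io.write_json(manifest, out / "derivation_manifest.json")
    return signatures, manifest


def run_training(config: PipelineConfig, expression: pd.DataFrame,
                 response: pd.DataFrame,
                 signatures: Mapping[str, DrugEfficacySignature],
                 ) -> dict[str, CVReport]:
    """Score the training cohort and cross-validate models per drug."""
    reports: dict[str, CVReport] = {}
    with _stage("train"):
        for j, (drug, sig) in enumerate(signatures.items()):
            auc = response[drug].dropna()
            shared = expression.columns.intersection(auc.index)
            scores = score_matrix(expression[shared], sig,
                                  method=config.scoring_method,
                                  panel=config.panel())["total_score"]
            reports[drug] = cross_validate(
                scores.to_numpy(), auc[shared].to_numpy(),
                methods=config.methods, k=config.cv_k,
                repeats=config.cv_repeats,
                seed=child_seed(config.seed, "train", j), drug_id=drug)
    return reports


def run_validation(config: PipelineConfig,
                   test_datasets: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
                   signatures: Mapping[str, DrugEfficacySignature],
                   models: Mapping[str, object] | None = None,
                   training_samples: Sequence[str] = (),
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score and evaluate every (drug, test dataset) pair, then tier drugs.

    ``test_datasets`` maps dataset id -> (expression, response) frames.
    When a fitted model is available for a drug its predictions are
    evaluated; otherwise the raw signature score is used (rank metrics
    are unaffected by the monotone linear map). With
    ``config.drop_overlap`` samples named in ``training_samples`` are
    removed from every test set first.

    Returns the per-(drug, dataset) evaluation table and the per-drug
    confidence-call table.
    """
    if not test_datasets:
        raise ValueError("no test datasets supplied")
    evals: list[DatasetEvaluation] = []
    with _stage("evaluate"):
        for dataset_id, (expr, resp) in test_datasets.items():
            for drug, sig in signatures.items():
                if drug not in resp.columns:
                    logger.info("dataset %s lacks drug %s; skipped",
                                dataset_id, drug)
                    continue
                auc = resp[drug].dropna()
                shared = expr.columns.intersection(auc.index)
                if config.drop_overlap and len(training_samples):
                    shared = shared.difference(pd.Index(training_samples))
                if len(shared) < 3:
                    logger.warning("dataset %s drug %s: %d shared samples; "
                                   "skipped", dataset_id, drug, len(shared))
                    continue
                scores = score_matrix(expr[shared], sig,
                                      method=config.scoring_method,
                                      panel=config.panel())["total_score"]
                model = (models or {}).get(drug)
                predicted = (np.asarray(model.predict(scores.to_numpy()))
                             if model is not None else scores.to_numpy())
                evals.append(evaluate_predictions(
                    predicted, auc[shared].to_numpy(), drug, dataset_id))
    eval_table = pd.DataFrame([vars(e) for e in evals])
    calls = []
    for drug in {e.drug_id for e in evals}:
        drug_evals = [e for e in evals if e.drug_id == drug]
        call = classify_confidence(drug_evals, high_rho=config.high_rho,
                                   high_ci=config.high_ci,
                                   low_rho=config.low_rho,
                                   low_ci=config.low_ci)
        calls.append({"drug_id": drug, "tier": call.tier,
                      "n_datasets": len(drug_evals)})
    call_table = pd.DataFrame(calls).sort_values("drug_id").reset_index(drop=True)
    return eval_table, call_table
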