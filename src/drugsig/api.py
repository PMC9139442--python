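"""Model/Results front end for per-drug efficacy-signature analysis.

:class:`DrugEfficacyModel` bundles a training cohort (log-expression and
drug-response AUC) with the analysis settings; :meth:`fit` runs the full
chain — resampling signature derivation, single-sample scoring, and
repeated cross-validation of the score -> AUC prediction models — and
returns a :class:`DrugEfficacyResults` carrying the signature, the
training scores, per-method CV metrics with their dispersions, BIC for
the regression families, and a ``summary()`` table. New samples are
scored and predicted through the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .evaluation import DatasetEvaluation, evaluate_predictions, spearman_rho
from .models import ALL_METHODS, CVReport, PredictionModel
from .pipeline import PipelineConfig, run_derivation, run_training
from .scoring import StableGenePanel, score_matrix
from .signatures import DrugEfficacySignature, SignatureDerivationParams

__all__ = ["DrugEfficacyModel", "DrugEfficacyResults"]


class DrugEfficacyModel:
    """One drug's efficacy-signature analysis, statsmodels-style.

    Parameters
    ----------
    expression : pd.DataFrame
        Training log-expression, genes x samples.
    response : pd.Series or single-column pd.DataFrame
        AUC (activity area; higher = more sensitive) per sample.
    drug_id : str, optional
        Defaults to the response column/series name.
    derivation : SignatureDerivationParams, optional
    methods : sequence of str, optional
        Model families to cross-validate (default: all five).
    scoring_method : {"singscore", "stingscore"}
    stable_genes : list of str, optional
        Anchor panel, required for stingscore.

    Examples
    --------
    >>> from drugsig import simulate
    >>> cohort = simulate.generate_cohort(simulate.SyntheticConfig(seed=1))
    >>> model = DrugEfficacyModel(cohort.expression, cohort.response)
    >>> results = model.fit(seed=1)
    >>> print(results.summary())  # doctest: +SKIP
    """

    def __init__(self, expression: pd.DataFrame, response, drug_id=None,
                 derivation: SignatureDerivationParams | None = None,
                 methods=ALL_METHODS, scoring_method: str = "singscore",
                 stable_genes: list[str] | None = None,
                 cv_k: int = 3, cv_repeats: int = 20):
        if isinstance(response, pd.DataFrame):
            if response.shape[1] != 1:
                raise ValueError("response must hold exactly one drug")
            response = response.iloc[:, 0]
        self.drug_id = str(drug_id or response.name or "drug")
        response = response.rename(self.drug_id)
        shared = expression.columns.intersection(response.dropna().index)
        if len(shared) < 7:
            raise ValueError("need at least 7 samples with expression and AUC")
        self.expression = expression[shared]
        self.response = response[shared].astype(float)
        self.derivation = derivation or SignatureDerivationParams()
        self.methods = list(methods)
        self.scoring_method = scoring_method
        self.stable_genes = list(stable_genes or [])
        self.cv_k = cv_k
        self.cv_repeats = cv_repeats

    @classmethod
    def from_dataframes(cls, expression: pd.DataFrame, response: pd.DataFrame,
                        drug_id: str, **kwargs) -> "DrugEfficacyModel":
        """Build from a multi-drug response table by naming the drug."""
        if drug_id not in response.columns:
            raise KeyError(f"drug {drug_id!r} not in response table")
        return cls(expression, response[drug_id], drug_id=drug_id, **kwargs)

    def _config(self, seed: int) -> PipelineConfig:
        return PipelineConfig(derivation=self.derivation,
                              scoring_method=self.scoring_method,
                              stable_genes=self.stable_genes,
                              methods=self.methods, cv_k=self.cv_k,
                              cv_repeats=self.cv_repeats, seed=seed)

    def fit(self, seed: int | None = None) -> "DrugEfficacyResults":
        """Derive the signature, score the cohort, cross-validate models."""
        seed = self.derivation.seed if seed is None else int(seed)
        config = self._config(seed)
        response_table = self.response.to_frame()
        signatures, manifest = run_derivation(config, self.expression,
                                              response_table)
        if self.drug_id not in signatures:
            raise RuntimeError("signature derivation failed for this drug")
        signature = signatures[self.drug_id]
        scores = score_matrix(self.expression, signature,
                              method=self.scoring_method,
                              panel=config.panel())["total_score"]
        cv = run_training(config, self.expression, response_table,
                          {self.drug_id: signature})[self.drug_id]
        return DrugEfficacyResults(model=self, signature=signature,
                                   scores=scores, cv_report=cv, seed=seed,
                                   manifest=manifest)


@dataclass
class DrugEfficacyResults:
    """Fitted signature, scores, and cross-validated prediction models."""

    model: DrugEfficacyModel
    signature: DrugEfficacySignature
    scores: pd.Series
    cv_report: CVReport
    seed: int
    manifest: dict = field(default_factory=dict, repr=False)

    @property
    def training_rho(self) -> float:
        """Spearman rho between training scores and observed AUC."""
        return spearman_rho(self.scores.to_numpy(),
                            self.model.response.to_numpy())

    def final_model(self, method: str = "linear") -> PredictionModel:
        return self.cv_report.final_models[method]

    def score_samples(self, expression: pd.DataFrame) -> pd.Series:
        """Signature scores for new samples (genes x samples matrix)."""
        panel = (StableGenePanel(self.model.stable_genes)
                 if self.model.stable_genes else None)
        return score_matrix(expression, self.signature,
                            method=self.model.scoring_method,
                            panel=panel)["total_score"]

    def predict(self, expression: pd.DataFrame,
                method: str = "linear") -> pd.Series:
        """Predicted AUC for new samples via the chosen fitted model."""
        scores = self.score_samples(expression)
        pred = self.final_model(method).predict(scores.to_numpy())
        return pd.Series(pred, index=scores.index, name="predicted_auc")

    def evaluate(self, expression: pd.DataFrame, response: pd.Series,
                 dataset_id: str = "test",
                 method: str = "linear") -> DatasetEvaluation:
        """Predicted-vs-observed agreement on an independent dataset."""
        auc = pd.Series(response).dropna()
        shared = expression.columns.intersection(auc.index)
        if len(shared) < 3:
            raise ValueError("need at least 3 evaluable samples")
        pred = self.predict(expression[shared], method=method)
        return evaluate_predictions(pred.to_numpy(), auc[shared].to_numpy(),
                                    self.model.drug_id, dataset_id)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        sig = self.signature
        lines = [
            "Drug efficacy signature analysis",
            "=" * 64,
            f"drug:                {self.model.drug_id}",
            f"samples (train):     {len(self.model.response)}",
            f"genes scored:        {self.model.expression.shape[0]}",
            f"scoring method:      {self.model.scoring_method}",
            (f"signature size:      {len(sig)} "
             f"(up {len(sig.up_genes)}, down {len(sig.down_genes)})"),
            f"training Spearman:   {self.training_rho:.3f}",
            f"seed:                {self.seed}",
            "",
            "Cross-validation (selected hyperparameters per method)",
            "-" * 64,
            f"{'method':<12}{'RMSE':>10}{'+/-':>8}{'MAE':>10}{'R2':>8}{'BIC':>10}",
        ]
        sel = self.cv_report.metrics[self.cv_report.metrics["selected"]]
        for row in sel.itertuples():
            bic = self.cv_report.bic.get(row.method)
            bic_s = f"{bic:>10.1f}" if bic is not None else f"{'-':>10}"
            lines.append(f"{row.method:<12}{row.rmse_mean:>10.4f}"
                         f"{row.rmse_sd:>8.4f}{row.mae_mean:>10.4f}"
                         f"{row.r2_mean:>8.3f}{bic_s}")
        lines.append("-" * 64)
        lines.append(f"best method by CV RMSE: {self.cv_report.best_method()}")
        return "\n".join(lines)
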