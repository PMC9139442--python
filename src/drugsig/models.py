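"""Per-drug prediction models mapping signature score to drug response.

The single input feature is the drug's own efficacy-signature score; the
target is the AUC (activity area) on [0, 1]. Five model families are
supported: ordinary least-squares linear and quadratic regression, and
epsilon-SVR with linear, polynomial, and radial (RBF) kernels. Model and
hyperparameter selection uses repeated k-fold cross-validation (3 folds x
20 repeats by default) with mean held-out RMSE as the criterion; all
methods see identical seeded partitions so they are compared on the same
splits. The Bayesian information criterion, BIC = n·ln(RSS/n) + p·ln(n),
compares the two regression families.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVR

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionModel",
    "CVReport",
    "fit_model",
    "cross_validate",
    "bic",
    "DEFAULT_SVM_GRIDS",
    "REGRESSION_METHODS",
    "SVM_METHODS",
]

REGRESSION_METHODS = ("linear", "quadratic")
SVM_METHODS = ("svm_linear", "svm_poly", "svm_rbf")
ALL_METHODS = REGRESSION_METHODS + SVM_METHODS

#: small logarithmic hyperparameter grids for the SVR variants
DEFAULT_SVM_GRIDS: dict[str, list[dict]] = {
    "svm_linear": [{"C": c, "epsilon": e}
                   for c in (0.1, 1.0, 10.0) for e in (0.01, 0.1)],
    "svm_poly": [{"C": c, "epsilon": e, "degree": d, "gamma": "scale"}
                 for c in (0.1, 1.0, 10.0) for e in (0.01, 0.1) for d in (2, 3)],
    "svm_rbf": [{"C": c, "epsilon": e, "gamma": g}
                for c in (0.1, 1.0, 10.0) for e in (0.01, 0.1)
                for g in ("scale", 1.0)],
}


@dataclass
class PredictionModel:
    """A fitted score -> AUC mapping for one drug."""

    drug_id: str
    method: str
    hyperparameters: dict = field(default_factory=dict)
    coefficients: list[float] | None = None  # regression: [intercept, b1, (b2)]
    _svr: SVR | None = field(default=None, repr=False)
    train_rmse: float | None = None
    train_mae: float | None = None
    train_r2: float | None = None
    n_train: int | None = None

    def predict(self, scores: Sequence[float]) -> np.ndarray:
        x = np.asarray(scores, dtype=float).reshape(-1)
        if self.method in REGRESSION_METHODS:
            coef = np.asarray(self.coefficients, dtype=float)
            design = _design(x, self.method, n_coef=len(coef))
            return design @ coef
        if self._svr is None:
            raise RuntimeError("SVR model not fitted")
        return self._svr.predict(x.reshape(-1, 1))

    def to_dict(self) -> dict:
        d = {"drug_id": self.drug_id, "method": self.method,
             "hyperparameters": self.hyperparameters,
             "train_rmse": self.train_rmse, "train_mae": self.train_mae,
             "train_r2": self.train_r2, "n_train": self.n_train}
        if self.method in REGRESSION_METHODS:
            d["coefficients"] = self.coefficients
        elif self._svr is not None:
            d["support_vectors"] = self._svr.support_vectors_.ravel().tolist()
            d["dual_coef"] = self._svr.dual_coef_.ravel().tolist()
            d["intercept"] = float(self._svr.intercept_[0])
        return d


@dataclass
class CVReport:
    """Cross-validation metrics and the selected configuration per method."""

    metrics: pd.DataFrame  # one row per (method, hyperparameters)
    chosen: dict[str, dict]  # method -> best hyperparameters
    final_models: dict[str, PredictionModel]
    bic: dict[str, float] = field(default_factory=dict)
    k: int = 3
    repeats: int = 20

    def best_method(self) -> str:
        """Method with the lowest selected mean CV RMSE."""
        sel = self.metrics[self.metrics["selected"]]
        return sel.sort_values("rmse_mean").iloc[0]["method"]


def _design(x: np.ndarray, method: str, n_coef: int | None = None) -> np.ndarray:
    cols = [np.ones_like(x), x]
    if method == "quadratic":
        cols.append(x ** 2)
    design = np.column_stack(cols)
    if n_coef is not None and design.shape[1] != n_coef:
        # degenerate fit (intercept-only) stored fewer coefficients
        design = design[:, :n_coef]
    return design


def _metrics(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float, float]:
    resid = pred - obs
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return rmse, mae, r2


def fit_model(scores: Sequence[float], auc: Sequence[float], method: str,
              hyperparameters: Mapping | None = None,
              drug_id: str = "drug") -> PredictionModel:
    """Fit one model family on the full training data.

    Constant (zero-variance) scores degrade the regression families to an
    intercept-only fit with a warning; SVR refuses them.
    """
    x = np.asarray(scores, dtype=float).reshape(-1)
    y = np.asarray(auc, dtype=float).reshape(-1)
    if len(x) != len(y):
        raise ValueError("scores and auc must be aligned")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if method not in ALL_METHODS:
        raise ValueError(f"unknown method {method!r}")
    hp = dict(hyperparameters or {})

    model = PredictionModel(drug_id=drug_id, method=method, hyperparameters=hp,
                            n_train=len(x))
    degenerate = np.ptp(x) == 0
    if method in REGRESSION_METHODS:
        if degenerate:
            warnings.warn("constant scores: fitting intercept-only model")
            model.coefficients = [float(y.mean())]
        else:
            design = _design(x, method)
            reg = LinearRegression(fit_intercept=False).fit(design, y)
            model.coefficients = [float(c) for c in reg.coef_]
    else:
        if degenerate:
            raise ValueError("constant scores: SVR cannot be fitted")
        kernel = {"svm_linear": "linear", "svm_poly": "poly",
                  "svm_rbf": "rbf"}[method]
        model._svr = SVR(kernel=kernel, **hp).fit(x.reshape(-1, 1), y)
    pred = model.predict(x)
    model.train_rmse, model.train_mae, model.train_r2 = _metrics(pred, y)
    return model


def repeated_kfold_indices(n: int, k: int, repeats: int, seed: int,
                           ) -> list[list[np.ndarray]]:
    """Seeded near-equal partitions: one list of k folds per repeat."""
    if n < k:
        raise ValueError("need at least k samples")
    rng = np.random.default_rng(seed)
    partitions = []
    for _ in range(repeats):
        perm = rng.permutation(n)
        partitions.append([np.sort(f) for f in np.array_split(perm, k)])
    return partitions


def cross_validate(scores: Sequence[float], auc: Sequence[float],
                   methods: Sequence[str] = ALL_METHODS,
                   grids: Mapping[str, list[dict]] | None = None,
                   k: int = 3, repeats: int = 20, seed: int = 0,
                   drug_id: str = "drug",
                   return_oof: bool = False) -> CVReport:
    """Repeated k-fold CV over methods and hyperparameter grids.

    Every method/hyperparameter combination is evaluated on the same
    seeded partitions. Per combination the mean and SD of held-out RMSE,
    MAE and R² across all k x repeats fold evaluations are reported; the
    combination with the lowest mean RMSE is selected per method and a
    final model is refitted on all data. BIC is attached for the
    regression families.

    ``return_oof=True`` additionally stores, per method, the out-of-fold
    prediction matrix (repeats x n) of the selected hyperparameters under
    ``report.oof`` — handy for leakage diagnostics.
    """
    x = np.asarray(scores, dtype=float).reshape(-1)
    y = np.asarray(auc, dtype=float).reshape(-1)
    grids = dict(grids or {})
    for method in methods:
        if method not in grids:
            grids[method] = (DEFAULT_SVM_GRIDS[method] if method in SVM_METHODS
                             else [{}])
        if not grids[method]:
            raise ValueError(f"empty hyperparameter grid for {method!r}")

    partitions = repeated_kfold_indices(len(x), k, repeats, seed)
    rows = []
    oof: dict[str, np.ndarray] = {}
    chosen: dict[str, dict] = {}
    final: dict[str, PredictionModel] = {}
    bic_values: dict[str, float] = {}
    for method in methods:
        best = None
        for hp_id, hp in enumerate(grids[method]):
            fold_rmse, fold_mae, fold_r2 = [], [], []
            oof_pred = np.full((repeats, len(x)), np.nan)
            for r, folds in enumerate(partitions):
                for held_out in folds:
                    train = np.setdiff1d(np.arange(len(x)), held_out)
                    fitted = fit_model(x[train], y[train], method, hp,
                                       drug_id=drug_id)
                    pred = fitted.predict(x[held_out])
                    oof_pred[r, held_out] = pred
                    rmse, mae, r2 = _metrics(pred, y[held_out])
                    fold_rmse.append(rmse)
                    fold_mae.append(mae)
                    fold_r2.append(r2)
            row = {"method": method, "hyperparameters": repr(hp), "hp_id": hp_id,
                   "rmse_mean": float(np.mean(fold_rmse)),
                   "rmse_sd": float(np.std(fold_rmse, ddof=1)),
                   "mae_mean": float(np.mean(fold_mae)),
                   "mae_sd": float(np.std(fold_mae, ddof=1)),
                   "r2_mean": float(np.nanmean(fold_r2)),
                   "r2_sd": float(np.nanstd(fold_r2, ddof=1))}
            rows.append(row)
            if best is None or row["rmse_mean"] < best[0]:
                best = (row["rmse_mean"], hp_id, hp, oof_pred)
        assert best is not None
        chosen[method] = best[2]
        if return_oof:
            oof[method] = best[3]
        final[method] = fit_model(x, y, method, best[2], drug_id=drug_id)
        if method in REGRESSION_METHODS:
            bic_values[method] = bic(final[method], x, y)

    metrics = pd.DataFrame(rows)
    metrics["selected"] = [
        chosen[r.method] == grids[r.method][r.hp_id] for r in metrics.itertuples()]
    report = CVReport(metrics=metrics, chosen=chosen, final_models=final,
                      bic=bic_values, k=k, repeats=repeats)
    if return_oof:
        report.oof = oof  # type: ignore[attr-defined]
    return report


def bic(model: PredictionModel, scores: Sequence[float],
        auc: Sequence[float]) -> float:
    """Gaussian-likelihood BIC = n·ln(RSS/n) + p·ln(n) for regression fits.

    A perfect fit (RSS = 0) returns -inf with a warning.
    """
    if model.method not in REGRESSION_METHODS:
        raise ValueError("BIC is defined here for the regression families only")
    x = np.asarray(scores, dtype=float).reshape(-1)
    y = np.asarray(auc, dtype=float).reshape(-1)
    rss = float(np.sum((model.predict(x) - y) ** 2))
    n = len(x)
    p = len(model.coefficients or [])
    # numerically-zero RSS (perfect interpolation up to float rounding)
    if rss <= n * np.finfo(float).eps ** 2 * max(1.0, float(y @ y)):
        warnings.warn("zero residual sum of squares: BIC is -inf")
        return float("-inf")
    return n * float(np.log(rss / n)) + p * float(np.log(n))
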