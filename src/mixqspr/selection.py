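"""Descriptor selection and MLR fitting.

The modeling engine is sequential forward selection over a correlation-
prefiltered feature pool.  At every step the candidate that maximizes a
configurable score (R2, negative MAE, or negative mean Poisson deviance,
each evaluated in-sample or by k-fold cross-validation) is proposed, but
it enters the model only if it reduces the leave-one-out cross-validated
mean absolute error (MAE_LOO) by at least a configured percentage
relative to the current model; the first rejection terminates selection.
This stopping rule keeps every accepted descriptor demonstrably useful —
no descriptor is force-fed into the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .features import MixtureFeatureMatrix

logger = logging.getLogger(__name__)

SCORING_METHODS = ("R2", "NMAE", "NMPD")


@dataclass
class SfsConfig:
    """Configuration of the forward-selection run.

    ``cv_folds`` of 0 means no cross-validation (candidates are scored
    in-sample on the training rows); 5 or 10 gives k-fold scoring on
    contiguous folds of a seeded permutation.
    """

    scoring: str = "R2"
    cv_folds: int = 0
    max_steps: int = 10
    pct_mae_reduction: float = 5.0
    corr_cutoff: float = 0.95
    cv_shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if self.scoring not in SCORING_METHODS:
            raise ValueError(f"scoring must be one of {SCORING_METHODS}")
        if self.cv_folds not in (0, 5, 10):
            raise ValueError("cv_folds must be 0 (none), 5 or 10")
        if not (0 < self.corr_cutoff <= 1):
            raise ValueError("corr_cutoff must be in (0, 1]")
        if self.pct_mae_reduction < 0:
            raise ValueError("pct_mae_reduction must be >= 0")


@dataclass
class FittedModel:
    """An ordinary-least-squares model on a selected descriptor subset."""

    selected_features: list[str]
    intercept: float
    coefficients: pd.Series  # indexed by feature name
    std_errors: pd.Series  # intercept + features
    n_train: int
    R2: float
    R2_adj: float
    F_statistic: float
    df_model: int
    df_resid: int
    max_intercorrelation: float
    model_id: str | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected_features if f not in X.columns]
        if missing:
            raise KeyError(f"feature columns missing from matrix: {missing}")
        if not self.selected_features:
            return np.full(len(X), self.intercept)
        return (
            self.intercept
            + X[self.selected_features].to_numpy(float) @ self.coefficients.to_numpy()
        )

    def equation(self, precision: int = 4) -> str:
        """Human-readable model equation with per-coefficient standard errors."""
        se = self.std_errors
        terms = [f"{self.intercept:+.{precision}f}(±{se.iloc[0]:.{precision}f})"]
        for name in self.selected_features:
            terms.append(
                f"{self.coefficients[name]:+.{precision}f}"
                f"(±{se[name]:.{precision}f}) {name}"
            )
        return "y = " + " ".join(terms)

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            selected_features=list(d["selected_features"]),
            intercept=float(d["intercept"]),
            coefficients=pd.Series(d["coefficients"], dtype=float),
            std_errors=pd.Series(d["std_errors"], dtype=float),
            n_train=int(d["n_train"]),
            R2=float(d["R2"]),
            R2_adj=float(d["R2_adj"]),
            F_statistic=float(d["F_statistic"]),
            df_model=int(d["df_model"]),
            df_resid=int(d["df_resid"]),
            max_intercorrelation=float(d["max_intercorrelation"]),
            model_id=d.get("model_id"),
        )

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "selected_features": self.selected_features,
            "intercept": self.intercept,
            "coefficients": self.coefficients.to_dict(),
            "std_errors": self.std_errors.to_dict(),
            "n_train": self.n_train,
            "R2": self.R2,
            "R2_adj": self.R2_adj,
            "F_statistic": self.F_statistic,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "max_intercorrelation": self.max_intercorrelation,
        }


# ---------------------------------------------------------------------------
# low-level OLS helpers shared with the validation modules

def design_matrix(X: pd.DataFrame, features: list[str]) -> np.ndarray:
    """Intercept-augmented design matrix for a feature subset."""
    n = len(X)
    if not features:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), X[list(features)].to_numpy(float)])


def ols_beta(Xa: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    return beta


def loo_residuals(Xa: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out prediction residuals via the hat-matrix identity.

    For OLS, the residual of point i under the model refit without i is
    e_i / (1 - h_ii); this avoids n refits and is exact.
    """
    XtX = Xa.T @ Xa
    beta = np.linalg.solve(XtX, Xa.T @ y)
    resid = y - Xa @ beta
    h = np.einsum("ij,jk,ik->i", Xa, np.linalg.inv(XtX), Xa)
    denom = 1.0 - h
    if np.any(denom <= 1e-12):
        raise np.linalg.LinAlgError(
            "leverage of 1 encountered: a point is uniquely determined by the fit"
        )
    return resid / denom


def loo_mae(X: pd.DataFrame, y: np.ndarray, features: list[str]) -> float:
    """MAE of leave-one-out predictions for a feature subset.

    With an empty subset the reference is the intercept-only model, whose
    LOO prediction for each left-out point is the mean of the remaining
    responses.
    """
    Xa = design_matrix(X, features)
    return float(np.mean(np.abs(loo_residuals(Xa, np.asarray(y, float)))))


# ---------------------------------------------------------------------------

def score(y_true: np.ndarray, y_pred: np.ndarray, scoring: str) -> float:
    """Model score under one of the supported criteria (higher is better).

    * ``R2``   — coefficient of determination.
    * ``NMAE`` — negative mean absolute error.
    * ``NMPD`` — negative mean Poisson deviance,
      ``-(1/n) * sum 2*[y*ln(y/yhat) - y + yhat]``; requires strictly
      positive observed and predicted values.
    """
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if len(y_true) != len(y_pred) or len(y_true) < 2:
        raise ValueError("y_true and y_pred must share length >= 2")
    if scoring == "R2":
        ss_tot = np.sum((y_true - y_true.mean()) ** 2)
        return float(1.0 - np.sum((y_true - y_pred) ** 2) / ss_tot)
    if scoring == "NMAE":
        return float(-np.mean(np.abs(y_true - y_pred)))
    if scoring == "NMPD":
        if np.any(y_true <= 0) or np.any(y_pred <= 0):
            raise ValueError("NMPD requires strictly positive observed and predicted values")
        dev = 2.0 * (y_true * np.log(y_true / y_pred) - y_true + y_pred)
        return float(-np.mean(dev))
    raise ValueError(f"unknown scoring {scoring!r}")


def prefilter_correlated(
    matrix: MixtureFeatureMatrix, corr_cutoff: float = 0.95
) -> tuple[MixtureFeatureMatrix, list[tuple[str, str]]]:
    """Drop features so no surviving pair exceeds ``|r| > corr_cutoff``.

    Deterministic greedy scan in column order: each column is kept unless
    its absolute Pearson correlation with an already-kept column exceeds
    the cutoff, in which case the later column is dropped.  Returns the
    reduced matrix and a removal log of (dropped, kept-partner) pairs.
    """
    X = matrix.X
    if X.shape[1] < 2:
        raise ValueError("need at least 2 feature columns")
    if (X.std(ddof=0) == 0).any():
        const = X.columns[(X.std(ddof=0) == 0)].tolist()
        raise ValueError(
            f"constant columns {const} have undefined correlation; "
            "apply drop_degenerate_columns first"
        )
    corr = X.corr().abs().to_numpy()
    cols = list(X.columns)
    kept: list[int] = []
    removed: list[tuple[str, str]] = []
    for j in range(len(cols)):
        partner = next((i for i in kept if corr[i, j] > corr_cutoff), None)
        if partner is None:
            kept.append(j)
        else:
            removed.append((cols[j], cols[partner]))
    reduced = MixtureFeatureMatrix(
        X.iloc[:, kept].copy(), matrix.y.copy(), matrix.record_ids.copy()
    )
    if removed:
        logger.info("correlation prefilter removed %d columns: %s",
                    len(removed), [r[0] for r in removed])
    return reduced, removed


def _cv_score(
    X: pd.DataFrame, y: np.ndarray, features: list[str], config: SfsConfig
) -> float:
    """Score a candidate feature set under the configured CV scheme."""
    if config.cv_folds == 0:
        Xa = design_matrix(X, features)
        yhat = Xa @ ols_beta(Xa, y)
        return score(y, yhat, config.scoring)
    n = len(y)
    rng = np.random.default_rng(config.cv_shuffle_seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, config.cv_folds)
    Xa = design_matrix(X, features)
    scores = []
    for hold in folds:
        mask = np.ones(n, bool)
        mask[hold] = False
        beta = ols_beta(Xa[mask], y[mask])
        scores.append(score(y[hold], Xa[hold] @ beta, config.scoring))
    return float(np.mean(scores))


def sfs_mlr(
    train_matrix: MixtureFeatureMatrix, config: SfsConfig | None = None
) -> tuple[FittedModel, list[dict]]:
    """Sequential forward selection with the %MAE_LOO-reduction stopping rule.

    Returns the fitted model on the accepted features and a per-step trace
    (candidate scores, proposed feature, MAE_LOO before/after, decision).
    The reference model at step 1 is the intercept-only model.
    """
    config = config or SfsConfig()
    X = train_matrix.X
    y = train_matrix.y.to_numpy(float)
    n = len(y)
    if n <= config.max_steps + 1:
        raise ValueError("training set too small for the configured max_steps")

    pool = list(X.columns)
    current: list[str] = []
    current_mae = loo_mae(X, y, current)  # intercept-only LOO baseline
    factor = 1.0 - config.pct_mae_reduction / 100.0
    trace: list[dict] = []

    for step in range(1, config.max_steps + 1):
        remaining = [f for f in pool if f not in current]
        if not remaining:
            break
        best_feat, best_score = None, -np.inf
        cand_scores = {}
        for feat in remaining:  # column order => deterministic tie-break
            try:
                s = _cv_score(X, y, current + [feat], config)
            except np.linalg.LinAlgError:
                continue
            cand_scores[feat] = s
            if s > best_score:
                best_feat, best_score = feat, s
        if best_feat is None:
            break
        new_mae = loo_mae(X, y, current + [best_feat])
        # a zero reduction requirement disables the stopping rule: plain
        # greedy selection truncated only by max_steps
        accepted = (
            config.pct_mae_reduction == 0 or new_mae <= factor * current_mae
        )
        trace.append(
            {
                "step": step,
                "proposed": best_feat,
                "score": best_score,
                "candidate_scores": cand_scores,
                "mae_loo_before": current_mae,
                "mae_loo_after": new_mae,
                "accepted": accepted,
            }
        )
        if not accepted:
            break
        current.append(best_feat)
        current_mae = new_mae

    if not current:
        logger.warning("no descriptor passed the %%MAE_LOO test; "
                       "returning intercept-only model")
    return fit_mlr(train_matrix, current), trace


def fit_mlr(train_matrix: MixtureFeatureMatrix, features: list[str]) -> FittedModel:
    """Ordinary least squares on a fixed feature subset.

    Reports coefficients with standard errors, R2, adjusted R2, the model
    F statistic, and the largest absolute pairwise correlation among the
    selected descriptors.
    """
    X = train_matrix.X
    y = train_matrix.y.to_numpy(float)
    features = list(features)
    Xa = design_matrix(X, features)
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise np.linalg.LinAlgError(
            f"design matrix rank-deficient for features {features}"
        )
    res = sm.OLS(y, Xa).fit()
    names = ["intercept"] + features
    if len(features) >= 2:
        sub = X[features].corr().abs().to_numpy()
        max_inc = float(np.max(sub[~np.eye(len(features), dtype=bool)]))
    else:
        max_inc = 0.0
    if features:
        r2, r2_adj, fstat = float(res.rsquared), float(res.rsquared_adj), float(res.fvalue)
    else:  # intercept-only: statsmodels leaves these undefined
        r2, r2_adj, fstat = 0.0, 0.0, float("nan")
    return FittedModel(
        selected_features=features,
        intercept=float(res.params[0]),
        coefficients=pd.Series(res.params[1:], index=features, dtype=float),
        std_errors=pd.Series(res.bse, index=names, dtype=float),
        n_train=len(y),
        R2=r2,
        R2_adj=r2_adj,
        F_statistic=fstat,
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        max_intercorrelation=max_inc,
    )
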