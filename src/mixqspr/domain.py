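"""Leverage-based applicability domain (Williams plot) and similarity thresholds.

A query point is a *structural outlier* when its leverage
``h = x (X'X)^-1 x'`` (intercept-augmented) exceeds the warning threshold
``h* = 3(p+1)/n``; a *response outlier* when its standardized residual
exceeds 3 in magnitude.  The standardized residual scale is the training
residual standard error with n - p - 1 degrees of freedom, applied to all
folds.  The similarity threshold used by consensus qualification is the
mean plus three sample standard deviations of the pairwise Euclidean
distances between training points in z-scored feature space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .features import MixtureFeatureMatrix
from .selection import FittedModel, design_matrix

logger = logging.getLogger(__name__)


@dataclass
class AdReport:
    """Applicability-domain summary for one model and one or two folds."""

    table: pd.DataFrame  # record_id, fold, h, SDR, is_structural_outlier, is_response_outlier
    h_star: float
    n_train: int
    p: int

    def outlier_counts(self) -> pd.DataFrame:
        return self.table.groupby("fold")[
            ["is_structural_outlier", "is_response_outlier"]
        ].sum()


def leverage_threshold(n_train: int, p: int) -> float:
    """Warning leverage ``h* = 3(p+1)/n`` for n training points, p features."""
    if n_train <= p + 1:
        raise ValueError("n_train must exceed p + 1")
    return 3.0 * (p + 1) / n_train


def leverages(
    train_design: np.ndarray, query_design: np.ndarray | None = None
) -> np.ndarray:
    """Leverage of each query row against the training design.

    Both designs must already include the intercept column; with no query,
    training self-leverages (the hat-matrix diagonal) are returned.
    """
    train_design = np.asarray(train_design, float)
    if np.linalg.matrix_rank(train_design) < train_design.shape[1]:
        raise np.linalg.LinAlgError("training design is rank-deficient")
    xtx_inv = np.linalg.inv(train_design.T @ train_design)
    q = train_design if query_design is None else np.asarray(query_design, float)
    return np.einsum("ij,jk,ik->i", q, xtx_inv, q)


def standardized_residuals(
    y: np.ndarray, yhat: np.ndarray, p: int, scale: float | None = None
) -> np.ndarray:
    """Residuals divided by the residual standard error.

    ``s = sqrt(RSS / (n - p - 1))`` computed from (y, yhat) unless an
    external ``scale`` is supplied (used to put test-set residuals on the
    training error scale).  A perfect fit yields all-zero residuals.
    """
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    resid = y - yhat
    if scale is None:
        n = len(y)
        if n <= p + 1:
            raise ValueError("need n > p + 1 for the residual standard error")
        scale = float(np.sqrt(np.sum(resid**2) / (n - p - 1)))
    if scale == 0:
        return np.zeros_like(resid)
    return resid / scale


def williams_data(
    model: FittedModel,
    train_matrix: MixtureFeatureMatrix,
    query_matrix: MixtureFeatureMatrix | None = None,
    sdr_cutoff: float = 3.0,
) -> AdReport:
    """Leverage / standardized-residual table behind a Williams plot.

    Training rows are always included (fold "train"); an optional query
    matrix (test or external set) is appended as fold "query".  Test
    residuals are standardized with the training residual standard error.
    """
    features = model.selected_features
    p = len(features)
    Xa_train = design_matrix(train_matrix.X, features)
    y_train = train_matrix.y.to_numpy(float)
    yhat_train = model.predict(train_matrix.X)
    h_star = leverage_threshold(len(y_train), p)

    resid_train = y_train - yhat_train
    s = float(np.sqrt(np.sum(resid_train**2) / (len(y_train) - p - 1)))
    rows = [
        pd.DataFrame(
            {
                "record_id": train_matrix.record_ids,
                "fold": "train",
                "h": leverages(Xa_train),
                "SDR": standardized_residuals(y_train, yhat_train, p, scale=s),
            }
        )
    ]
    if query_matrix is not None and len(query_matrix) > 0:
        Xa_q = design_matrix(query_matrix.X, features)
        y_q = query_matrix.y.to_numpy(float)
        rows.append(
            pd.DataFrame(
                {
                    "record_id": query_matrix.record_ids,
                    "fold": "query",
                    "h": leverages(Xa_train, Xa_q),
                    "SDR": standardized_residuals(
                        y_q, model.predict(query_matrix.X), p, scale=s
                    ),
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table["is_structural_outlier"] = table["h"] > h_star
    table["is_response_outlier"] = table["SDR"].abs() > sdr_cutoff
    return AdReport(table=table, h_star=h_star, n_train=len(y_train), p=p)


def similarity_threshold(
    train_features: pd.DataFrame,
) -> tuple[float, float, float]:
    """Mean + 3*SD rule on pairwise Euclidean distances.

    Features are z-scored with the training statistics; zero-variance
    columns carry no distance information and are excluded with a note.
    Returns (mean distance, sample SD, threshold).
    """
    X = train_features.astype(float)
    if len(X) < 2:
        raise ValueError("need at least 2 training rows")
    sd = X.std(ddof=1)
    degenerate = sd.index[sd == 0].tolist()
    if degenerate:
        logger.info("excluding zero-variance features from distances: %s", degenerate)
        X = X.drop(columns=degenerate)
        sd = sd.drop(degenerate)
    if X.shape[1] == 0:
        return 0.0, 0.0, 0.0
    Z = (X - X.mean()) / sd
    d = pdist(Z.to_numpy())
    mean = float(d.mean())
    spread = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return mean, spread, mean + 3.0 * spread
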