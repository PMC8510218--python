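"""Intelligent consensus prediction over an ensemble of mixture MLR models.

Four combination rules are supported:

* **CM0** — arithmetic mean of all member predictions (plain consensus).
* **CM1** — arithmetic mean over the *qualified* members only.
* **CM2** — weighted mean over qualified members, weights proportional to
  the inverse of each member's cross-validated MAE on the training
  records most similar to the test record.
* **CM3** — compound-wise best selection: for each test record, the
  prediction of the qualified member with the smallest similar-compound
  cross-validated MAE.

A member is *qualified* for a test record when the record lies inside the
member's leverage applicability domain (h <= h*) and its distance to the
nearest training record, in z-scored union-of-member-features space, does
not exceed the training mean + 3*SD pairwise-distance threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .features import MixtureFeatureMatrix
from .metrics import external_metrics, loo_cv, rm2_metrics
from .selection import FittedModel, design_matrix
from .domain import leverage_threshold, leverages, similarity_threshold

logger = logging.getLogger(__name__)

METHODS = ("CM0", "CM1", "CM2", "CM3")


@dataclass
class ConsensusConfig:
    member_models: list[FittedModel]
    method: str = "CM0"
    n_similar: int = 10

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        min_members = 1 if self.method == "CM3" else 2
        if len(self.member_models) < min_members:
            raise ValueError(
                f"{self.method} needs at least {min_members} member model(s)"
            )
        if self.n_similar < 1:
            raise ValueError("n_similar must be positive")


@dataclass
class ConsensusResult:
    """Per-record consensus bookkeeping plus external metrics."""

    method: str
    table: pd.DataFrame  # per-record: member predictions, qualification, weights, choice
    predictions: np.ndarray
    metrics: dict


def predict_members(
    models: list[FittedModel], feature_matrix: MixtureFeatureMatrix
) -> pd.DataFrame:
    """Prediction table: one row per record, one column per member model."""
    cols = {}
    for j, model in enumerate(models):
        name = model.model_id or f"model{j}"
        missing = [f for f in model.selected_features
                   if f not in feature_matrix.X.columns]
        if missing:
            raise KeyError(f"model {name}: feature columns missing {missing}")
        cols[name] = model.predict(feature_matrix.X)
    return pd.DataFrame(cols)


def _union_feature_space(
    models: list[FittedModel], train_X: pd.DataFrame, query_X: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Z-score the union of member features with training statistics."""
    union: list[str] = []
    for m in models:
        for f in m.selected_features:
            if f not in union:
                union.append(f)
    if not union:
        raise ValueError("member models select no features")
    mu = train_X[union].mean()
    sd = train_X[union].std(ddof=1).replace(0.0, 1.0)
    Zt = ((train_X[union] - mu) / sd).to_numpy(float)
    Zq = ((query_X[union] - mu) / sd).to_numpy(float)
    return Zt, Zq, union


def per_record_model_quality(
    loo_abs_errors: np.ndarray,
    train_Z: np.ndarray,
    query_Z: np.ndarray,
    n_similar: int = 10,
) -> np.ndarray:
    """Similar-compound cross-validated MAE of one model for each query row.

    For every query row, the ``n_similar`` nearest training rows (Euclidean
    in the given z-scored space) are found and the mean of the model's LOO
    absolute errors over that neighborhood is returned.
    """
    n_train = train_Z.shape[0]
    k = min(n_similar, n_train)
    if k < n_similar:
        logger.warning("only %d training records available; using all", n_train)
    dist = cdist(query_Z, train_Z)
    idx = np.argsort(dist, axis=1, kind="stable")[:, :k]
    return np.asarray(loo_abs_errors, float)[idx].mean(axis=1)


def consensus_predict(
    config: ConsensusConfig,
    train_matrix: MixtureFeatureMatrix,
    test_matrix: MixtureFeatureMatrix,
    member_loo_errors: list[np.ndarray] | None = None,
) -> ConsensusResult:
    """Combine member predictions on a test set under the configured rule.

    By default each member's LOO absolute errors are obtained by refitting
    its feature set on ``train_matrix``; ensembles whose members were
    fitted on different data divisions can instead supply
    ``member_loo_errors`` (one array per member, aligned with the training
    rows) from their own validation history.
    """
    models = config.member_models
    names = [m.model_id or f"model{j}" for j, m in enumerate(models)]
    preds = predict_members(models, test_matrix)  # (n_test, n_members)
    P = preds.to_numpy(float)
    n_test, n_members = P.shape

    Zt, Zq, union = _union_feature_space(models, train_matrix.X, test_matrix.X)
    _, _, dist_threshold = similarity_threshold(train_matrix.X[union])
    nearest = cdist(Zq, Zt).min(axis=1)
    within_distance = nearest <= dist_threshold

    # member leverage domains
    qualified = np.zeros((n_test, n_members), bool)
    quality = np.zeros((n_test, n_members))
    for j, model in enumerate(models):
        feats = model.selected_features
        Xa_t = design_matrix(train_matrix.X, feats)
        Xa_q = design_matrix(test_matrix.X, feats)
        h_star = leverage_threshold(len(train_matrix), len(feats))
        h = leverages(Xa_t, Xa_q)
        qualified[:, j] = (h <= h_star) & within_distance
        if member_loo_errors is not None:
            loo_err = np.asarray(member_loo_errors[j], float)
        else:
            _, _, yhat_loo = loo_cv(train_matrix, feats)
            loo_err = np.abs(train_matrix.y.to_numpy(float) - yhat_loo)
        quality[:, j] = per_record_model_quality(loo_err, Zt, Zq, config.n_similar)

    # fall back to all members for records where nothing qualifies
    no_qual = ~qualified.any(axis=1)
    if no_qual.any():
        logger.info("%d records had no qualified member; using all members",
                    int(no_qual.sum()))
        qualified[no_qual, :] = True

    weights = np.zeros_like(P)
    chosen = np.full(n_test, -1)
    consensus = np.empty(n_test)
    for i in range(n_test):
        q = np.flatnonzero(qualified[i])
        if config.method == "CM0":
            consensus[i] = P[i].mean()
        elif config.method == "CM1":
            consensus[i] = P[i, q].mean()
            weights[i, q] = 1.0 / len(q)
        elif config.method == "CM2":
            mae = quality[i, q]
            if np.any(mae == 0):
                w = (mae == 0).astype(float)
            else:
                w = 1.0 / mae
            w = w / w.sum()
            weights[i, q] = w
            consensus[i] = float(P[i, q] @ w)
        else:  # CM3: best qualified member, ties to lower member index
            best = q[np.argmin(quality[i, q], )]
            chosen[i] = best
            consensus[i] = P[i, best]

    table = preds.copy()
    for j, name in enumerate(names):
        table[f"qualified_{name}"] = qualified[:, j]
        table[f"cv_mae_similar_{name}"] = quality[:, j]
        if config.method == "CM2":
            table[f"weight_{name}"] = weights[:, j]
    if config.method == "CM3":
        table["chosen_model"] = [names[c] if c >= 0 else None for c in chosen]
    table.insert(0, "record_id", test_matrix.record_ids.to_numpy())
    table["consensus"] = consensus

    y_train = train_matrix.y.to_numpy(float)
    y_test = test_matrix.y.to_numpy(float)
    metrics: dict = {
        "MAE_test": float(np.mean(np.abs(y_test - consensus))),
    }
    try:
        r2_pred, mae_test, aard = external_metrics(y_train, y_test, consensus)
        metrics.update(R2_pred=r2_pred, MAE_test=mae_test, AARD_test_pct=aard)
    except ValueError as exc:  # e.g. no test variance around the training mean
        logger.info("external metrics unavailable: %s", exc)
    if len(y_test) >= 3 and np.std(y_test) > 0 and np.std(consensus) > 0:
        metrics["rm2_test"], metrics["delta_rm2_test"] = rm2_metrics(y_test, consensus)
    return ConsensusResult(
        method=config.method, table=table, predictions=consensus, metrics=metrics
    )
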