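"""Internal and external validation battery for mixture MLR models.

Internal predictivity is measured by leave-one-out cross-validation
(Q2_LOO, MAE_LOO) and by the stricter *leave-chemical-out* scheme
(Q2_LCO, MAE_LCO), which removes — one chemical at a time — every mixture
containing that chemical, refits on the remainder with the same feature
set, and predicts the removed records; the component-1 (HBA) and
component-2 (HBD) passes are averaged.  A large gap between the LOO and
LCO statistics signals that the model does not generalize across at least
one of the component families.

External predictivity uses Q2_F1 (variance explained relative to the
training mean), MAE_test, the percent absolute average relative deviation
(%AARD), and the rm2 metrics built from observed-versus-predicted
regression lines with and without intercept.  Robustness against chance
correlation is checked by Y-randomization (refitting on shuffled
responses) summarized as cR2_P.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import MixtureFeatureMatrix
from .selection import FittedModel, design_matrix, fit_mlr, loo_residuals, ols_beta

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    """The full metric battery for one fitted model."""

    Q2_LOO: float
    MAE_LOO: float
    Q2_LCO: float | None = None
    MAE_LCO: float | None = None
    R2_pred: float | None = None  # alias Q2_F1
    MAE_test: float | None = None
    AARD_train_pct: float | None = None
    AARD_test_pct: float | None = None
    rm2_loo: float | None = None
    delta_rm2_loo: float | None = None
    rm2_test: float | None = None
    delta_rm2_test: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class LcoDetail:
    """Per-chemical bookkeeping of the leave-chemical-out passes."""

    # one entry per removed chemical: (chemical_id, slot, removed positions)
    removals: list[tuple[str, str, np.ndarray]]
    yhat_comp1: np.ndarray  # each training record predicted once per pass
    yhat_comp2: np.ndarray
    y_mean: float
    n_train: int


@dataclass
class RandomizationReport:
    """Y-randomization summary; ``variant`` names the cR2_P formula used."""

    n_runs: int
    R2_original: float
    R2_randomized: np.ndarray
    cRp2: float
    variant: str


def loo_cv(
    train_matrix: MixtureFeatureMatrix, features: list[str]
) -> tuple[float, float, np.ndarray]:
    """Leave-one-out cross-validation with a frozen feature set.

    Returns (Q2_LOO, MAE_LOO, per-record LOO predictions).  Uses the exact
    hat-matrix identity rather than n refits.
    """
    y = train_matrix.y.to_numpy(float)
    features = list(features)
    if len(y) <= len(features) + 2:
        raise ValueError("too few training records for LOO with this feature count")
    Xa = design_matrix(train_matrix.X, features)
    e_loo = loo_residuals(Xa, y)
    yhat = y - e_loo
    press = float(np.sum(e_loo**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss_tot, float(np.mean(np.abs(e_loo))), yhat


def lco_cv(
    train_matrix: MixtureFeatureMatrix,
    train_records: pd.DataFrame,
    features: list[str],
    skip_unevaluable: bool = False,
) -> tuple[float, float, LcoDetail]:
    """Leave-chemical-out cross-validation.

    ``train_records`` must align row-for-row with ``train_matrix`` and
    provide ``comp1_id`` / ``comp2_id``.  For each unique chemical in each
    component slot, all its records are removed, the model is refit on the
    remainder (same features), and the removed records are predicted.
    Q2_LCO averages the two Q2-style terms (with the fixed training mean),
    MAE_LCO averages the two mean-absolute-error terms.
    """
    if len(train_records) != len(train_matrix):
        raise ValueError("train_records must align with train_matrix")
    y = train_matrix.y.to_numpy(float)
    features = list(features)
    n = len(y)
    y_mean = float(y.mean())
    Xa = design_matrix(train_matrix.X, features)

    removals: list[tuple[str, str, np.ndarray]] = []
    yhat_passes: dict[str, np.ndarray] = {}
    for slot, column in (("comp1", "comp1_id"), ("comp2", "comp2_id")):
        yhat = np.full(n, np.nan)
        ids = train_records[column].to_numpy()
        for cid in pd.unique(ids):
            out = np.flatnonzero(ids == cid)
            keep = np.flatnonzero(ids != cid)
            if len(keep) < len(features) + 2:
                msg = (f"removing {slot} chemical {cid!r} leaves too few "
                       f"records ({len(keep)}) to refit")
                if skip_unevaluable:
                    logger.warning("%s; skipped", msg)
                    continue
                raise ValueError(msg)
            beta = ols_beta(Xa[keep], y[keep])
            yhat[out] = Xa[out] @ beta
            removals.append((str(cid), slot, out))
        yhat_passes[slot] = yhat

    q2_terms, mae_terms = [], []
    ss_tot = float(np.sum((y - y_mean) ** 2))
    for slot in ("comp1", "comp2"):
        yhat = yhat_passes[slot]
        mask = ~np.isnan(yhat)
        q2_terms.append(1.0 - float(np.sum((y[mask] - yhat[mask]) ** 2)) / ss_tot)
        mae_terms.append(float(np.sum(np.abs(y[mask] - yhat[mask]))) / n)
    detail = LcoDetail(
        removals=removals,
        yhat_comp1=yhat_passes["comp1"],
        yhat_comp2=yhat_passes["comp2"],
        y_mean=y_mean,
        n_train=n,
    )
    return float(np.mean(q2_terms)), float(np.mean(mae_terms)), detail


def external_metrics(
    y_train: np.ndarray, y_test: np.ndarray, yhat_test: np.ndarray
) -> tuple[float, float, float]:
    """External-set predictivity: (R2_pred a.k.a. Q2_F1, MAE_test, %AARD).

    Q2_F1 benchmarks squared test errors against deviations of the test
    observations from the *training* mean, so a model predicting the
    training mean everywhere scores exactly zero.
    """
    y_train = np.asarray(y_train, float)
    y_test = np.asarray(y_test, float)
    yhat_test = np.asarray(yhat_test, float)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    denom = float(np.sum((y_test - y_train.mean()) ** 2))
    if denom == 0:
        raise ValueError("test responses show no variance around the training mean")
    r2_pred = 1.0 - float(np.sum((y_test - yhat_test) ** 2)) / denom
    mae = float(np.mean(np.abs(y_test - yhat_test)))
    if np.any(y_test <= 0):
        raise ValueError("%AARD requires strictly positive observed values")
    aard = float(100.0 * np.mean(np.abs(y_test - yhat_test) / y_test))
    return r2_pred, mae, aard


def aard_pct(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Percent absolute average relative deviation, (100/n) * sum |y-yhat|/y."""
    y_obs = np.asarray(y_obs, float)
    if np.any(y_obs <= 0):
        raise ValueError("%AARD requires strictly positive observed values")
    return float(100.0 * np.mean(np.abs(y_obs - np.asarray(y_pred, float)) / y_obs))


def _r0_squared(y: np.ndarray, x: np.ndarray) -> float:
    """Determination coefficient of the through-origin least-squares line
    predicting y from x, benchmarked against the mean of y."""
    k = float(np.sum(x * y) / np.sum(x * x))
    ss_res = float(np.sum((y - k * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def rm2_metrics(
    y_obs: np.ndarray, y_pred: np.ndarray, scaled: bool = False
) -> tuple[float, float]:
    """Average rm2 and delta-rm2 from observed-versus-predicted regressions.

    rm2 penalizes predictions that correlate with the observations but
    deviate from the identity line: with r2 the squared Pearson
    correlation and r0_2 the determination coefficient of the zero-
    intercept regression line, ``rm2 = r2 * (1 - sqrt(r2 - r0_2))``; the
    primed variant swaps the regression axes.  Returns the mean of the two
    variants and their absolute difference.  With ``scaled=True`` both
    vectors are min-max scaled to [0, 1] before the regressions.
    """
    y_obs = np.asarray(y_obs, float)
    y_pred = np.asarray(y_pred, float)
    if len(y_obs) < 3:
        raise ValueError("rm2 metrics need at least 3 points")
    if np.std(y_obs) == 0 or np.std(y_pred) == 0:
        raise ValueError("degenerate variance in observed or predicted values")
    if scaled:
        y_obs = (y_obs - y_obs.min()) / (y_obs.max() - y_obs.min())
        y_pred = (y_pred - y_pred.min()) / (y_pred.max() - y_pred.min())

    r2 = float(np.corrcoef(y_obs, y_pred)[0, 1] ** 2)
    r0_fwd = _r0_squared(y_obs, y_pred)
    r0_rev = _r0_squared(y_pred, y_obs)

    def _rm2(r0: float) -> float:
        rad = r2 - r0
        if rad < 0:  # numerically possible when r0 exceeds r2
            logger.info("rm2 radicand %.3e clamped to 0", rad)
            rad = 0.0
        return r2 * (1.0 - np.sqrt(rad))

    rm2_fwd, rm2_rev = _rm2(r0_fwd), _rm2(r0_rev)
    return float((rm2_fwd + rm2_rev) / 2.0), float(abs(rm2_fwd - rm2_rev))


def y_randomization(
    train_matrix: MixtureFeatureMatrix,
    features: list[str],
    n_runs: int = 100,
    rng_seed: int = 0,
    variant: str = "as_printed",
) -> RandomizationReport:
    """Fit the same feature set against shuffled responses.

    ``cR2_P`` compares the true fit R2 with the mean randomized fit:
    the default (``as_printed``) form is ``R * (R2 - mean Rr2)``, the
    ``sqrt`` variant is ``sqrt(R2 * (R2 - mean Rr2))``.  Values above 0.5
    indicate the model is unlikely to arise from chance correlation.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if variant not in ("as_printed", "sqrt"):
        raise ValueError("variant must be 'as_printed' or 'sqrt'")
    y = train_matrix.y.to_numpy(float)
    features = list(features)
    Xa = design_matrix(train_matrix.X, features)

    def _r2(yy: np.ndarray) -> float:
        beta = ols_beta(Xa, yy)
        resid = yy - Xa @ beta
        return 1.0 - float(np.sum(resid**2) / np.sum((yy - yy.mean()) ** 2))

    r2_orig = _r2(y)
    rng = np.random.default_rng(rng_seed)
    rr2 = np.array([_r2(rng.permutation(y)) for _ in range(n_runs)])
    diff = r2_orig - float(rr2.mean())
    if variant == "as_printed":
        crp2 = float(np.sqrt(max(r2_orig, 0.0)) * diff)
    else:
        crp2 = float(np.sqrt(max(r2_orig * diff, 0.0)))
    return RandomizationReport(
        n_runs=n_runs,
        R2_original=r2_orig,
        R2_randomized=rr2,
        cRp2=crp2,
        variant=variant,
    )


def validate_model(
    model: FittedModel,
    train_matrix: MixtureFeatureMatrix,
    train_records: pd.DataFrame | None = None,
    test_matrix: MixtureFeatureMatrix | None = None,
    rm2_scaled: bool = False,
) -> ValidationReport:
    """Assemble the full validation battery for a fitted model.

    LCO metrics are filled only if ``train_records`` is given; external
    metrics only if ``test_matrix`` is given.
    """
    features = model.selected_features
    y_train = train_matrix.y.to_numpy(float)
    q2_loo, mae_loo, yhat_loo = loo_cv(train_matrix, features)
    report = ValidationReport(Q2_LOO=q2_loo, MAE_LOO=mae_loo)
    report.AARD_train_pct = aard_pct(y_train, model.predict(train_matrix.X))
    if np.std(yhat_loo) > 0:
        report.rm2_loo, report.delta_rm2_loo = rm2_metrics(
            y_train, yhat_loo, scaled=rm2_scaled
        )
    if train_records is not None:
        report.Q2_LCO, report.MAE_LCO, _ = lco_cv(train_matrix, train_records, features)
    if test_matrix is not None and len(test_matrix) > 0:
        yhat_test = model.predict(test_matrix.X)
        y_test = test_matrix.y.to_numpy(float)
        report.R2_pred, report.MAE_test, report.AARD_test_pct = external_metrics(
            y_train, y_test, yhat_test
        )
        if len(y_test) >= 3 and np.std(y_test) > 0 and np.std(yhat_test) > 0:
            report.rm2_test, report.delta_rm2_test = rm2_metrics(
                y_test, yhat_test, scaled=rm2_scaled
            )
    return report
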