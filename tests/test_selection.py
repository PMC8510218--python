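import itertools

import numpy as np
import pandas as pd
import pytest

from mixqspr.features import MixtureFeatureMatrix
from mixqspr.selection import (
    SfsConfig,
    design_matrix,
    fit_mlr,
    loo_mae,
    prefilter_correlated,
    score,
    sfs_mlr,
)


def matrix_from(X: pd.DataFrame, y) -> MixtureFeatureMatrix:
    return MixtureFeatureMatrix(
        X, pd.Series(np.asarray(y, float)),
        pd.Series([f"r{i}" for i in range(len(X))]),
    )


# --- correlation prefilter -------------------------------------------------

def test_prefilter_keeps_one_of_two_identical_columns():
    rng = np.random.default_rng(0)
    a = rng.normal(size=30)
    m = matrix_from(pd.DataFrame({"a": a, "b": 2 * a + 1, "c": rng.normal(size=30)}),
                    rng.normal(size=30))
    reduced, removed = prefilter_correlated(m, 0.95)
    assert reduced.feature_names == ["a", "c"]
    assert removed == [("b", "a")]


def test_prefilter_identity_below_threshold():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
    reduced, removed = prefilter_correlated(matrix_from(X, rng.normal(size=40)), 0.95)
    assert removed == []
    assert reduced.feature_names == ["a", "b", "c"]


def test_prefilter_three_mutually_correlated_columns():
    rng = np.random.default_rng(2)
    base = rng.normal(size=50)
    X = pd.DataFrame({
        "a": base,
        "b": base + rng.normal(scale=1e-3, size=50),
        "c": -base + rng.normal(scale=1e-3, size=50),
    })
    reduced, removed = prefilter_correlated(matrix_from(X, rng.normal(size=50)), 0.95)
    assert reduced.feature_names == ["a"]
    assert [r[0] for r in removed] == ["b", "c"]
    # survivors never exceed the cutoff pairwise
    assert (reduced.X.corr().abs().to_numpy()[~np.eye(1, dtype=bool)] <= 0.95).all()


def test_prefilter_rejects_constant_columns():
    m = matrix_from(pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]}),
                    [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="drop_degenerate_columns"):
        prefilter_correlated(m, 0.95)


# --- scoring ---------------------------------------------------------------

@pytest.mark.parametrize(
    "y, yhat, scoring, expected",
    [
        ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), "R2", 1.0),
        ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), "NMAE", 0.0),
        ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), "NMPD", 0.0),
        ((1.0, 2.0, 3.0), (1.0, 2.0, 4.0), "NMAE", -1.0 / 3.0),
        ((1.0, 2.0, 3.0), (2.0, 2.0, 2.0), "R2", 0.0),  # mean predictor
    ],
)
def test_score_examples(y, yhat, scoring, expected):
    assert score(np.array(y), np.array(yhat), scoring) == pytest.approx(expected, abs=1e-12)


def test_nmpd_matches_poisson_deviance_formula():
    y = np.array([1.0, 2.0, 3.0])
    yhat = np.array([1.5, 1.5, 3.5])
    dev = 2 * (y * np.log(y / yhat) - y + yhat)
    assert score(y, yhat, "NMPD") == pytest.approx(-dev.mean(), abs=1e-12)


def test_nmpd_rejects_non_positive_values():
    with pytest.raises(ValueError, match="positive"):
        score(np.array([1.0, -1.0, 2.0]), np.array([1.0, 1.0, 1.0]), "NMPD")


# --- OLS fitting -----------------------------------------------------------

def test_exact_line_recovered():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    m = matrix_from(pd.DataFrame({"x": x}), 3.0 + 2.0 * x)
    model = fit_mlr(m, ["x"])
    assert model.intercept == pytest.approx(3.0, abs=1e-10)
    assert model.coefficients["x"] == pytest.approx(2.0, abs=1e-10)
    assert model.R2 == pytest.approx(1.0, abs=1e-12)


def test_ols_matches_normal_equations_oracle():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(25, 2)), columns=["f1", "f2"])
    y = 1.0 + 0.5 * X["f1"] - 0.2 * X["f2"] + rng.normal(scale=0.1, size=25)
    model = fit_mlr(matrix_from(X, y), ["f1", "f2"])
    Xa = np.column_stack([np.ones(25), X.to_numpy()])
    beta = np.linalg.solve(Xa.T @ Xa, Xa.T @ y.to_numpy())
    assert model.intercept == pytest.approx(beta[0], abs=1e-10)
    assert model.coefficients.to_numpy() == pytest.approx(beta[1:], abs=1e-10)
    # standard errors from the explicit covariance of the normal equations
    resid = y.to_numpy() - Xa @ beta
    s2 = resid @ resid / (25 - 3)
    se = np.sqrt(np.diag(s2 * np.linalg.inv(Xa.T @ Xa)))
    assert model.std_errors.to_numpy() == pytest.approx(se, abs=1e-10)


def test_orthogonal_features_have_zero_intercorrelation():
    X = pd.DataFrame({"f1": [1.0, 1.0, -1.0, -1.0], "f2": [1.0, -1.0, 1.0, -1.0]})
    model = fit_mlr(matrix_from(X, [1.0, 2.0, 3.0, 4.0]), ["f1", "f2"])
    assert model.max_intercorrelation == pytest.approx(0.0, abs=1e-12)


def test_rank_deficiency_is_an_error():
    X = pd.DataFrame({"f1": [1.0, 2.0, 3.0, 4.0], "f2": [2.0, 4.0, 6.0, 8.0]})
    with pytest.raises(np.linalg.LinAlgError):
        fit_mlr(matrix_from(X, [1.0, 2.0, 3.0, 4.0]), ["f1", "f2"])


# --- sequential forward selection ------------------------------------------

def brute_force_greedy(X, y, max_steps):
    """Independent greedy forward search maximizing in-sample R2."""
    selected = []
    for _ in range(max_steps):
        remaining = [c for c in X.columns if c not in selected]
        if not remaining:
            break
        best, best_r2 = None, -np.inf
        for c in remaining:
            Xa = np.column_stack([np.ones(len(y))] + [X[f] for f in selected + [c]])
            beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
            resid = y - Xa @ beta
            r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
            if r2 > best_r2:
                best, best_r2 = c, r2
        selected.append(best)
    return selected


def test_sfs_with_zero_threshold_matches_brute_force_greedy():
    rng = np.random.default_rng(4)
    X = pd.DataFrame(rng.normal(size=(60, 8)), columns=[f"f{i}" for i in range(8)])
    y = (0.9 * X["f2"] - 0.6 * X["f5"] + 0.3 * X["f0"]
         + rng.normal(scale=0.3, size=60)).to_numpy()
    cfg = SfsConfig(scoring="R2", cv_folds=0, max_steps=8, pct_mae_reduction=0.0)
    model, trace = sfs_mlr(matrix_from(X, y), cfg)
    assert model.selected_features == brute_force_greedy(X, y, 8)


def test_sfs_recovers_planted_two_feature_model():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(size=(120, 10)), columns=[f"f{i}" for i in range(10)])
    y = (2.0 * X["f1"] - 3.0 * X["f2"] + rng.normal(scale=0.05, size=120)).to_numpy()
    model, _ = sfs_mlr(matrix_from(X, y), SfsConfig())
    assert set(model.selected_features) == {"f1", "f2"}
    assert model.coefficients["f1"] == pytest.approx(2.0, abs=0.05)
    assert model.coefficients["f2"] == pytest.approx(-3.0, abs=0.05)


def test_sfs_on_pure_noise_returns_intercept_only():
    rng = np.random.default_rng(6)
    X = pd.DataFrame(rng.normal(size=(200, 8)), columns=[f"f{i}" for i in range(8)])
    y = rng.normal(size=200)
    model, trace = sfs_mlr(matrix_from(X, y), SfsConfig())
    assert model.selected_features == []
    assert trace and not trace[-1]["accepted"]


def test_accepted_trace_shows_required_mae_reduction():
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.normal(size=(100, 6)), columns=[f"f{i}" for i in range(6)])
    y = (1.5 * X["f0"] - 1.0 * X["f3"] + 0.7 * X["f5"]
         + rng.normal(scale=0.05, size=100)).to_numpy()
    cfg = SfsConfig(pct_mae_reduction=5.0)
    _, trace = sfs_mlr(matrix_from(X, y), cfg)
    for step in trace:
        if step["accepted"]:
            assert step["mae_loo_after"] <= 0.95 * step["mae_loo_before"]


def test_larger_max_steps_extends_accepted_prefix():
    rng = np.random.default_rng(8)
    X = pd.DataFrame(rng.normal(size=(150, 12)), columns=[f"f{i}" for i in range(12)])
    coefs = np.linspace(2.0, 0.4, 6)
    y = (X.iloc[:, :6].to_numpy() @ coefs
         + rng.normal(scale=0.02, size=150))
    short, _ = sfs_mlr(matrix_from(X, y), SfsConfig(max_steps=3, pct_mae_reduction=0.0))
    long, _ = sfs_mlr(matrix_from(X, y), SfsConfig(max_steps=6, pct_mae_reduction=0.0))
    assert long.selected_features[:3] == short.selected_features
    assert len(short.selected_features) == 3


def test_intercept_only_loo_baseline_is_mean_of_remaining():
    y = np.array([1.0, 2.0, 3.0, 6.0])
    X = pd.DataFrame({"f0": [0.0, 1.0, 0.0, 1.0]})
    expected = np.mean([abs(yi - np.delete(y, i).mean()) for i, yi in enumerate(y)])
    assert loo_mae(X, y, []) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("cv", [5, 10])
def test_kfold_scoring_is_deterministic(cv):
    rng = np.random.default_rng(9)
    X = pd.DataFrame(rng.normal(size=(80, 5)), columns=[f"f{i}" for i in range(5)])
    y = (X["f1"] + rng.normal(scale=0.2, size=80)).to_numpy()
    cfg = SfsConfig(scoring="NMAE", cv_folds=cv)
    a, _ = sfs_mlr(matrix_from(X, y), cfg)
    b, _ = sfs_mlr(matrix_from(X, y), cfg)
    assert a.selected_features == b.selected_features
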