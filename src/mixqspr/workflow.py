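"""End-to-end grid driver: featurize, enumerate splits, train, validate, rank.

Mirrors the one-directional modeling workflow: build the weighted-mixture
feature matrix once, enumerate every retained mixtures-out/compounds-out
division over a (seed, interval) grid, train an SFS-MLR model per
division x (scoring, CV) configuration, validate each, and rank the
survivors by the average of MAE_LOO and MAE_test after discarding models
with excessive descriptor intercollinearity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import MixtureFeatureMatrix, compute_wm_features, drop_degenerate_columns
from .io import MixtureDataset
from .metrics import validate_model
from .selection import FittedModel, SfsConfig, prefilter_correlated, sfs_mlr
from .splitting import DataSplit, enumerate_co_splits, enumerate_mo_splits

logger = logging.getLogger(__name__)


@dataclass
class GridConfig:
    """The model-development grid."""

    max_seed: int = 3
    max_interval: int = 3
    min_test_fraction: float = 0.20
    scorings: tuple[str, ...] = ("R2",)
    cv_options: tuple[int, ...] = (0,)
    max_steps: int = 10
    pct_mae_reduction: float = 5.0
    corr_cutoff: float = 0.95


@dataclass
class GridRun:
    summary: pd.DataFrame
    models: dict[str, FittedModel]
    splits: dict[str, DataSplit]
    traces: dict[str, list]


def run_grid(
    dataset: MixtureDataset,
    strategies: tuple[str, ...] = ("MO", "CO"),
    grid_config: GridConfig | None = None,
    feature_mode: str = "both",
) -> GridRun:
    """Train and validate one model per retained split x configuration.

    Model ids are "<STRATEGY><seq>" in deterministic grid order
    (strategy, then split enumeration order, then scoring, then CV).
    Individual model failures are logged and skipped.
    """
    cfg = grid_config or GridConfig()
    matrix = drop_degenerate_columns(compute_wm_features(dataset, mode=feature_mode))

    splits: list[DataSplit] = []
    if "MO" in strategies:
        splits += enumerate_mo_splits(
            dataset, cfg.max_seed, cfg.max_interval, cfg.min_test_fraction
        )
    if "CO" in strategies:
        splits += enumerate_co_splits(
            dataset, cfg.max_seed, cfg.max_interval, cfg.min_test_fraction
        )

    rows = []
    models: dict[str, FittedModel] = {}
    kept_splits: dict[str, DataSplit] = {}
    traces: dict[str, list] = {}
    counters = {"MO": 0, "CO": 0}
    for split in splits:
        train = matrix.subset(split.train_idx)
        test = matrix.subset(split.test_idx)
        train_records = dataset.records.iloc[split.train_idx].reset_index(drop=True)
        for scoring in cfg.scorings:
            for cv in cfg.cv_options:
                counters[split.strategy] += 1
                model_id = f"{split.strategy}{counters[split.strategy]}"
                sfs_cfg = SfsConfig(
                    scoring=scoring,
                    cv_folds=cv,
                    max_steps=cfg.max_steps,
                    pct_mae_reduction=cfg.pct_mae_reduction,
                    corr_cutoff=cfg.corr_cutoff,
                )
                try:
                    # columns constant within this training fold break the
                    # correlation prefilter and OLS
                    clean = drop_degenerate_columns(train)
                    reduced, _ = prefilter_correlated(clean, cfg.corr_cutoff)
                    model, trace = sfs_mlr(reduced, sfs_cfg)
                    model.model_id = model_id
                    report = validate_model(
                        model, train, train_records=train_records, test_matrix=test
                    )
                except Exception as exc:  # individual failures are not fatal
                    logger.warning("model %s failed: %s", model_id, exc)
                    continue
                models[model_id] = model
                kept_splits[model_id] = split
                traces[model_id] = trace
                rows.append(
                    {
                        "model_id": model_id,
                        "strategy": split.strategy,
                        "seed": split.seed,
                        "interval": split.interval,
                        "scoring": scoring,
                        "cv": cv,
                        "n_features": len(model.selected_features),
                        "n_train": split.n_train,
                        "n_test": split.n_test,
                        "Q2_LOO": report.Q2_LOO,
                        "Q2_LCO": report.Q2_LCO,
                        "MAE_LOO": report.MAE_LOO,
                        "R2_pred": report.R2_pred,
                        "MAE_test": report.MAE_test,
                        "max_intercorrelation": model.max_intercorrelation,
                    }
                )
    summary = pd.DataFrame(rows)
    if not summary.empty:
        summary = summary.sort_values("MAE_LOO", kind="stable").reset_index(drop=True)
    return GridRun(summary=summary, models=models, splits=kept_splits, traces=traces)


def rank_and_select(
    summary: pd.DataFrame, k: int = 3, max_intercorrelation_cutoff: float = 0.80
) -> pd.DataFrame:
    """Shortlist models: drop high-intercollinearity ones, rank the rest by
    the mean of MAE_LOO and MAE_test (ascending), return the top k."""
    if summary.empty:
        raise ValueError("empty model summary")
    ok = summary[summary["max_intercorrelation"] <= max_intercorrelation_cutoff].copy()
    if ok.empty:
        logger.warning("all models exceed the intercorrelation cutoff")
        return ok
    ok["mae_mean"] = (ok["MAE_LOO"] + ok["MAE_test"]) / 2.0
    return ok.sort_values("mae_mean", kind="stable").head(k).reset_index(drop=True)
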