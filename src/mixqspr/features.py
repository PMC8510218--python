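"""Molar-fraction-weighted mixture descriptors.

For each base descriptor d with per-component values D1 (component 1) and
D2 (component 2), two mixture features can be formed for a data point with
mole fractions (x1, x2):

* sum form        ``d_pmix = x1*D1 + x2*D2``
* difference form ``d_nmix = |x1*D1 - x2*D2|``

Both are symmetric under jointly swapping the component labels and their
fractions.  The feature matrix additionally carries three passthrough
columns taken verbatim from the mixture table: temperature ``T_K`` and
the two halide indicators ``has_Cl`` / ``has_Br``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MixtureDataset, SchemaError

logger = logging.getLogger(__name__)

PASSTHROUGH = ("T_K", "has_Cl", "has_Br")


@dataclass
class MixtureFeatureMatrix:
    """Weighted-mixture feature matrix aligned one-to-one with dataset records.

    ``X`` holds the feature columns, ``y`` the target, both sharing a
    positional index identical to the source dataset's record order.
    """

    X: pd.DataFrame
    y: pd.Series
    record_ids: pd.Series

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.record_ids)):
            raise ValueError("X, y and record_ids must be equally long")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, positions) -> "MixtureFeatureMatrix":
        pos = list(positions)
        return MixtureFeatureMatrix(
            self.X.iloc[pos].reset_index(drop=True),
            self.y.iloc[pos].reset_index(drop=True),
            self.record_ids.iloc[pos].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out.insert(0, "record_id", self.record_ids)
        out["y"] = self.y
        return out


def compute_wm_features(
    dataset: MixtureDataset, mode: str = "both"
) -> MixtureFeatureMatrix:
    """Build the weighted-mixture feature matrix from a dataset.

    Parameters
    ----------
    dataset:
        Validated binary-mixture dataset.
    mode:
        ``"pmix"`` (sum form only), ``"nmix"`` (absolute-difference form
        only) or ``"both"`` (default; final published mixture models use
        descriptors of both kinds).
    """
    if mode not in ("pmix", "nmix", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    rec = dataset.records
    table = dataset.component_table.frame
    names = dataset.component_table.descriptor_names
    if not names:
        raise SchemaError("component table has no descriptors")

    d1 = table.loc[rec["comp1_id"]].to_numpy(float)  # (n, p) component-1 vectors
    d2 = table.loc[rec["comp2_id"]].to_numpy(float)
    x1 = rec["x1"].to_numpy(float)[:, None]
    x2 = rec["x2"].to_numpy(float)[:, None]

    cols: dict[str, np.ndarray] = {}
    if mode in ("pmix", "both"):
        pmix = x1 * d1 + x2 * d2
        for j, name in enumerate(names):
            cols[f"{name}_pmix"] = pmix[:, j]
    if mode in ("nmix", "both"):
        nmix = np.abs(x1 * d1 - x2 * d2)
        for j, name in enumerate(names):
            cols[f"{name}_nmix"] = nmix[:, j]
    X = pd.DataFrame(cols)
    for col in PASSTHROUGH:
        X[col] = rec[col].to_numpy(float)
    return MixtureFeatureMatrix(
        X=X,
        y=rec["y"].astype(float).rename("y"),
        record_ids=rec["record_id"].rename("record_id"),
    )


def drop_degenerate_columns(
    matrix: MixtureFeatureMatrix, variance_floor: float = 0.0
) -> MixtureFeatureMatrix:
    """Remove feature columns whose variance is at or below ``variance_floor``.

    Constant columns are undefined under Pearson correlation and break the
    correlation prefilter and OLS, so they are dropped before modeling.
    """
    var = matrix.X.var(ddof=0)
    keep = var.index[var > variance_floor].tolist()
    dropped = [c for c in matrix.X.columns if c not in keep]
    if not keep:
        raise ValueError("all feature columns are degenerate")
    if dropped:
        logger.info("dropping degenerate columns: %s", dropped)
    return MixtureFeatureMatrix(
        matrix.X[keep].copy(), matrix.y.copy(), matrix.record_ids.copy()
    )
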