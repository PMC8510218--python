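"""Mixtures-out (MO) and compounds-out (CO) train/test divisions.

Both strategies enumerate many deterministic divisions from two small
integers, *seed* and *interval*:

* **MO** — unique mixtures are sorted by instance count (descending,
  stable); the mixture with the most instances is always kept in
  training; mixtures at sorted positions ``seed+1, seed+1+interval, ...``
  go wholly to the test set.
* **CO** — the same positional rule is applied independently to the
  unique component-1 chemicals and the unique component-2 chemicals
  (each sorted by record count, top element protected); every record
  containing ANY selected chemical goes to the test set, so selected
  chemicals are entirely unseen during training.

Divisions whose test set holds less than a minimum fraction of the
records (default 20%) are discarded.  Coinciding divisions produced by
different (seed, interval) pairs are deduplicated, retaining the
provenance of every generating pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import MixtureDataset, unique_mixtures

logger = logging.getLogger(__name__)


@dataclass
class DataSplit:
    """A train/test division with its generating provenance."""

    strategy: str  # "MO" or "CO"
    seed: int
    interval: int
    train_idx: np.ndarray  # positional indices into dataset.records
    test_idx: np.ndarray
    test_fraction: float
    #: all (seed, interval) pairs that generate this same division
    provenance: list[tuple[int, int]] = field(default_factory=list)
    #: CO only: chemicals whose records were sent to test
    selected_chemicals: tuple = ()
    #: MO only: mixture keys sent to test
    selected_mixtures: tuple = ()

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        if not self.provenance:
            self.provenance = [(self.seed, self.interval)]

    @property
    def n_train(self) -> int:
        return len(self.train_idx)

    @property
    def n_test(self) -> int:
        return len(self.test_idx)


def _positions(seed: int, interval: int, length: int) -> list[int]:
    """Sorted-list positions selected for the test side.

    Position 0 (the element with the most instances) is protected and
    always trains; selection starts at ``seed + 1`` and advances by
    ``interval``.
    """
    return list(range(seed + 1, length, interval))


def _finalize(
    splits: list[DataSplit], n_records: int, min_test_fraction: float
) -> list[DataSplit]:
    """Apply the test-size filter and deduplicate coinciding divisions."""
    kept: list[DataSplit] = []
    seen: dict[tuple, DataSplit] = {}
    for sp in splits:
        if sp.n_test == 0 or sp.n_train == 0:
            continue
        if sp.test_fraction < min_test_fraction:
            continue
        key = (tuple(sp.train_idx), tuple(sp.test_idx))
        if key in seen:
            seen[key].provenance.append((sp.seed, sp.interval))
        else:
            seen[key] = sp
            kept.append(sp)
    if not kept:
        logger.warning("no split survived the %.0f%% test-size filter",
                       100 * min_test_fraction)
    return kept


def enumerate_mo_splits(
    dataset: MixtureDataset,
    max_seed: int,
    max_interval: int,
    min_test_fraction: float = 0.20,
) -> list[DataSplit]:
    """Enumerate mixtures-out divisions over the (seed, interval) grid.

    Seeds run ``0..max_seed``, intervals ``1..max_interval``; output order
    is seed-major then interval, with duplicates merged.
    """
    mixtures = unique_mixtures(dataset)
    if len(mixtures) < 2:
        raise ValueError("need at least 2 unique mixtures for an MO split")
    keys = dataset.mixture_keys()
    n = len(dataset)
    key_rows = {k: np.flatnonzero((keys == k).to_numpy()) for k, _ in mixtures}

    raw: list[DataSplit] = []
    for seed in range(0, max_seed + 1):
        for interval in range(1, max_interval + 1):
            chosen = [mixtures[p][0] for p in _positions(seed, interval, len(mixtures))]
            if not chosen:
                continue
            test_idx = np.sort(np.concatenate([key_rows[k] for k in chosen]))
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            raw.append(
                DataSplit(
                    strategy="MO",
                    seed=seed,
                    interval=interval,
                    train_idx=train_idx,
                    test_idx=test_idx,
                    test_fraction=len(test_idx) / n,
                    selected_mixtures=tuple(chosen),
                )
            )
    return _finalize(raw, n, min_test_fraction)


def _chemical_counts(dataset: MixtureDataset, column: str) -> list[tuple[str, int]]:
    """Unique chemicals of one component slot, sorted by record count
    descending with first-occurrence tie-break."""
    col = dataset.records[column]
    counts: dict[str, int] = {}
    first: dict[str, int] = {}
    for pos, cid in enumerate(col):
        counts[cid] = counts.get(cid, 0) + 1
        first.setdefault(cid, pos)
    ordered = sorted(counts, key=lambda c: (-counts[c], first[c]))
    return [(c, counts[c]) for c in ordered]


def enumerate_co_splits(
    dataset: MixtureDataset,
    max_seed: int,
    max_interval: int,
    min_test_fraction: float = 0.20,
) -> list[DataSplit]:
    """Enumerate compounds-out divisions over the (seed, interval) grid.

    The positional selection rule is applied independently to the sorted
    component-1 and component-2 chemical lists; a record containing any
    selected chemical (in the matching slot) lands in the test set.
    """
    comp1 = _chemical_counts(dataset, "comp1_id")
    comp2 = _chemical_counts(dataset, "comp2_id")
    if len(comp1) < 2 or len(comp2) < 2:
        raise ValueError("need >=2 unique chemicals in each component slot")
    rec = dataset.records
    n = len(dataset)

    raw: list[DataSplit] = []
    for seed in range(0, max_seed + 1):
        for interval in range(1, max_interval + 1):
            sel1 = {comp1[p][0] for p in _positions(seed, interval, len(comp1))}
            sel2 = {comp2[p][0] for p in _positions(seed, interval, len(comp2))}
            if not sel1 and not sel2:
                continue
            in_test = rec["comp1_id"].isin(sel1) | rec["comp2_id"].isin(sel2)
            test_idx = np.flatnonzero(in_test.to_numpy())
            train_idx = np.flatnonzero(~in_test.to_numpy())
            raw.append(
                DataSplit(
                    strategy="CO",
                    seed=seed,
                    interval=interval,
                    train_idx=train_idx,
                    test_idx=test_idx,
                    test_fraction=len(test_idx) / n,
                    selected_chemicals=tuple(sorted(sel1) + sorted(sel2)),
                )
            )
    return _finalize(raw, n, min_test_fraction)


def describe_split(split: DataSplit, dataset: MixtureDataset) -> dict:
    """Summary counts per side plus the chemicals present only in test."""
    rec = dataset.records
    keys = dataset.mixture_keys()
    out = {}
    for fold, idx in (("train", split.train_idx), ("test", split.test_idx)):
        sub = rec.iloc[idx]
        out[fold] = {
            "n_records": len(idx),
            "n_mixtures": keys.iloc[idx].nunique() if len(idx) else 0,
            "n_comp1": sub["comp1_id"].nunique() if len(idx) else 0,
            "n_comp2": sub["comp2_id"].nunique() if len(idx) else 0,
        }
    train_chems = set(rec.iloc[split.train_idx]["comp1_id"]) | set(
        rec.iloc[split.train_idx]["comp2_id"]
    )
    test_chems = set(rec.iloc[split.test_idx]["comp1_id"]) | set(
        rec.iloc[split.test_idx]["comp2_id"]
    )
    out["chemicals_only_in_test"] = sorted(test_chems - train_chems)
    out["strategy"] = split.strategy
    out["seed"] = split.seed
    out["interval"] = split.interval
    out["test_fraction"] = split.test_fraction
    return out
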