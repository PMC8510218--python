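import numpy as np
import pandas as pd
import pytest

from mixqspr.io import ComponentDescriptorTable, MixtureDataset
from mixqspr.features import compute_wm_features, drop_degenerate_columns
from mixqspr.simulate import SyntheticSpec, generate


def make_dataset(rows, comp_values):
    """Build a MixtureDataset from (comp1, comp2, x1, x2, T, y) tuples.

    ``comp_values`` maps chemical id -> list of descriptor values; halide
    flags default to chloride for every acceptor.
    """
    n_desc = len(next(iter(comp_values.values())))
    table = ComponentDescriptorTable(
        pd.DataFrame(
            comp_values, index=[f"d{j + 1}" for j in range(n_desc)]
        ).T
    )
    records = pd.DataFrame(
        [
            {
                "record_id": f"r{i}",
                "comp1_id": c1,
                "comp2_id": c2,
                "x1": x1,
                "x2": x2,
                "T_K": t,
                "has_Cl": 1,
                "has_Br": 0,
                "y": y,
            }
            for i, (c1, c2, x1, x2, t, y) in enumerate(rows)
        ]
    )
    return MixtureDataset(records, table)


@pytest.fixture
def mo_toy_dataset():
    """Mixture instance counts A:5, B:4, C:3, D:2, E:1 (15 records)."""
    comp = {
        "HBA1": [1.0, 2.0],
        "HBA2": [3.0, 1.0],
        "HBA3": [2.0, 4.0],
        "HBD1": [0.5, 1.5],
        "HBD2": [2.5, 0.5],
    }
    rows = []
    mixtures = [
        ("HBA1", "HBD1", 5),  # A
        ("HBA1", "HBD2", 4),  # B
        ("HBA2", "HBD1", 3),  # C
        ("HBA2", "HBD2", 2),  # D
        ("HBA3", "HBD1", 1),  # E
    ]
    for c1, c2, count in mixtures:
        for k in range(count):
            t = 293.15 + 10 * k
            rows.append((c1, c2, 0.5, 0.5, t, 1.1 + 0.01 * k))
    return make_dataset(rows, comp)


@pytest.fixture
def co_toy_dataset():
    """Chemical record counts HBA1:8/HBA2:4 and HBD1:6/HBD2:4/HBD3:2."""
    comp = {
        "HBA1": [1.0, 2.0],
        "HBA2": [3.0, 1.0],
        "HBD1": [0.5, 1.5],
        "HBD2": [2.5, 0.5],
        "HBD3": [1.5, 3.0],
    }
    pairs = [
        ("HBA1", "HBD1", 4),
        ("HBA1", "HBD2", 3),
        ("HBA1", "HBD3", 1),
        ("HBA2", "HBD1", 2),
        ("HBA2", "HBD2", 1),
        ("HBA2", "HBD3", 1),
    ]
    rows = []
    for c1, c2, count in pairs:
        for k in range(count):
            rows.append((c1, c2, 0.5, 0.5, 293.15 + 10 * k, 1.05 + 0.02 * k))
    return make_dataset(rows, comp)


@pytest.fixture(scope="session")
def synth():
    """One default synthetic dataset with ground truth (480 records)."""
    dataset, truth = generate(SyntheticSpec(rng_seed=7))
    return dataset, truth


@pytest.fixture(scope="session")
def synth_matrix(synth):
    dataset, _ = synth
    return drop_degenerate_columns(compute_wm_features(dataset))


def naive_loo_predictions(X, y, features):
    """Refit-per-point LOO oracle (no hat-matrix shortcut)."""
    n = len(y)
    Xa = np.column_stack([np.ones(n), X[list(features)].to_numpy(float)]) \
        if features else np.ones((n, 1))
    y = np.asarray(y, float)
    out = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        beta, *_ = np.linalg.lstsq(Xa[mask], y[mask], rcond=None)
        out[i] = Xa[i] @ beta
    return out
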