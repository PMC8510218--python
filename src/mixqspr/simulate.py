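"""Synthetic binary-mixture datasets with known ground truth.

The generator emulates the structure of an experimental deep-eutectic-
solvent density compilation: a few tens of hydrogen-bond-acceptor and
hydrogen-bond-donor chemicals, combined at a handful of molar ratios,
each mixture measured over a temperature series.  The response is linear
in a small set of weighted-mixture descriptors plus a (by default
negative) temperature term, with additive Gaussian noise — exactly the
model family the selection engine assumes, so exact parameter recovery is
a meaningful end-to-end check.  It makes no attempt at physically
realistic densities or chemically meaningful descriptor correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import compute_wm_features
from .io import ComponentDescriptorTable, MixtureDataset


def _default_ratios() -> list[tuple[float, float]]:
    return [(0.5, 0.5), (2.0 / 3.0, 1.0 / 3.0)]


def _default_temperatures() -> list[float]:
    return [283.15, 303.15, 323.15, 343.15, 363.15]


@dataclass
class SyntheticSpec:
    """Study conditions of a synthetic dataset.

    Defaults give 8 acceptors x 6 donors x 2 molar ratios x 5
    temperatures = 480 records, a density-like intercept of 1.10 g/cm3, a
    negative temperature coefficient (densities fall with temperature)
    and measurement noise of 0.005 g/cm3.
    """

    n_comp1: int = 8
    n_comp2: int = 6
    n_descriptors: int = 6
    ratios: list[tuple[float, float]] = field(default_factory=_default_ratios)
    temperatures_K: list[float] = field(default_factory=_default_temperatures)
    true_features: tuple[str, ...] = ("desc1_pmix", "desc2_nmix", "desc3_pmix")
    true_coefficients: tuple[float, ...] = (0.08, -0.05, 0.04)
    temp_coefficient: float = -5.0e-4
    intercept: float = 1.10
    noise_sd: float = 0.005
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.true_features) != len(self.true_coefficients):
            raise ValueError("true_features and true_coefficients must align")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_records(self) -> int:
        return (
            self.n_comp1 * self.n_comp2 * len(self.ratios) * len(self.temperatures_K)
        )


def _draw_components(
    rng: np.random.Generator,
    prefix: str,
    count: int,
    n_desc: int,
    loc: np.ndarray,
    scale: np.ndarray,
    shift: float = 0.0,
) -> pd.DataFrame:
    names = [f"desc{j + 1}" for j in range(n_desc)]
    values = rng.normal(loc + shift, scale, size=(count, n_desc))
    ids = [f"{prefix}{i + 1:02d}" for i in range(count)]
    return pd.DataFrame(values, index=ids, columns=names)


def _assemble(
    spec: SyntheticSpec,
    comp_table: ComponentDescriptorTable,
    comp1_ids: list[str],
    comp2_ids: list[str],
    halides: dict[str, tuple[int, int]],
    temperatures: list[float],
    rng: np.random.Generator,
    id_prefix: str = "r",
) -> MixtureDataset:
    rows = []
    k = 0
    for c1 in comp1_ids:
        for c2 in comp2_ids:
            for x1, x2 in spec.ratios:
                for t in temperatures:
                    k += 1
                    cl, br = halides[c1]
                    rows.append(
                        {
                            "record_id": f"{id_prefix}{k:05d}",
                            "comp1_id": c1,
                            "comp2_id": c2,
                            "x1": x1,
                            "x2": x2,
                            "T_K": t,
                            "has_Cl": cl,
                            "has_Br": br,
                            "y": 1.0,  # placeholder until the response is drawn
                        }
                    )
    records = pd.DataFrame(rows)
    dataset = MixtureDataset(records, comp_table)
    matrix = compute_wm_features(dataset, mode="both")
    y = np.full(len(records), spec.intercept)
    for feat, coef in zip(spec.true_features, spec.true_coefficients):
        if feat not in matrix.X.columns:
            raise ValueError(f"true feature {feat!r} not among generated columns")
        y = y + coef * matrix.X[feat].to_numpy()
    y = y + spec.temp_coefficient * matrix.X["T_K"].to_numpy()
    y = y + rng.normal(0.0, spec.noise_sd, size=len(y))
    if np.any(y <= 0):
        raise ValueError("generated responses not strictly positive; "
                         "adjust intercept or coefficients")
    dataset.records["y"] = y
    return dataset


def _halide_flags(rng: np.random.Generator, comp1_ids: list[str]) -> dict:
    """Most acceptors are chloride salts, some bromide, some halide-free."""
    flags = {}
    for cid in comp1_ids:
        u = rng.random()
        flags[cid] = (1, 0) if u < 0.6 else ((0, 1) if u < 0.8 else (0, 0))
    return flags


def generate(spec: SyntheticSpec) -> tuple[MixtureDataset, dict]:
    """Generate a dataset and return it with its ground-truth record.

    Component descriptors are independent Gaussians with per-descriptor
    random location and scale; mixtures cover the full acceptor x donor
    cross product at every ratio, each with a full temperature series.
    """
    rng = np.random.default_rng(spec.rng_seed)
    loc = rng.uniform(1.0, 5.0, size=spec.n_descriptors)
    scale = rng.uniform(0.3, 1.0, size=spec.n_descriptors)
    comp1 = _draw_components(rng, "HBA", spec.n_comp1, spec.n_descriptors, loc, scale)
    comp2 = _draw_components(rng, "HBD", spec.n_comp2, spec.n_descriptors, loc, scale)
    table = ComponentDescriptorTable(pd.concat([comp1, comp2]))
    halides = _halide_flags(rng, list(comp1.index))
    dataset = _assemble(
        spec, table, list(comp1.index), list(comp2.index), halides,
        list(spec.temperatures_K), rng,
    )
    truth = {
        "intercept": spec.intercept,
        "coefficients": {
            **dict(zip(spec.true_features, spec.true_coefficients)),
            "T_K": spec.temp_coefficient,
        },
        "true_features": list(spec.true_features) + ["T_K"],
        "noise_sd": spec.noise_sd,
        "descriptor_loc": loc.tolist(),
        "descriptor_scale": scale.tolist(),
    }
    return dataset, truth


def perturb_external(
    dataset: MixtureDataset,
    spec: SyntheticSpec,
    n_new_comp1: int = 0,
    n_new_comp2: int = 0,
    descriptor_shift: float = 0.0,
    temperature_offset: float = 10.0,
) -> MixtureDataset:
    """External validation set obeying the same response law.

    New chemicals (if requested) get fresh descriptor vectors, optionally
    shifted by ``descriptor_shift`` (in descriptor units) to land outside
    the training descriptor ranges and trigger structural-outlier flags
    downstream.  With no new chemicals the external set reuses the
    existing chemicals at temperatures offset from the training grid.
    """
    rng = np.random.default_rng(spec.rng_seed + 1_000_003)
    # redraw the population parameters the training components came from
    base_rng = np.random.default_rng(spec.rng_seed)
    loc = base_rng.uniform(1.0, 5.0, size=spec.n_descriptors)
    scale = base_rng.uniform(0.3, 1.0, size=spec.n_descriptors)

    old = dataset.component_table.frame
    old_comp1 = sorted({r for r in dataset.records["comp1_id"]})
    old_comp2 = sorted({r for r in dataset.records["comp2_id"]})

    frames = [old]
    if n_new_comp1:
        new1 = _draw_components(
            rng, "xHBA", n_new_comp1, spec.n_descriptors, loc, scale, descriptor_shift
        )
        frames.append(new1)
        comp1_ids = list(new1.index)
    else:
        comp1_ids = old_comp1
    if n_new_comp2:
        new2 = _draw_components(
            rng, "xHBD", n_new_comp2, spec.n_descriptors, loc, scale, descriptor_shift
        )
        frames.append(new2)
        comp2_ids = list(new2.index)
    else:
        comp2_ids = old_comp2
    table = ComponentDescriptorTable(pd.concat(frames))

    halides = {}
    rec = dataset.records
    for cid in comp1_ids:
        if cid in set(rec["comp1_id"]):
            row = rec[rec["comp1_id"] == cid].iloc[0]
            halides[cid] = (int(row["has_Cl"]), int(row["has_Br"]))
    halides.update(_halide_flags(rng, [c for c in comp1_ids if c not in halides]))

    temps = [t + temperature_offset for t in spec.temperatures_K]
    return _assemble(
        spec, table, comp1_ids, comp2_ids, halides, temps, rng, id_prefix="x"
    )
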