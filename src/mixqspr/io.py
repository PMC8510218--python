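"""Data model and CSV readers/writers for binary-mixture datasets.

A dataset couples two tables:

* a *mixture table* — one row per experimental data point, giving the two
  component identities (component 1 is the hydrogen-bond acceptor or its
  cationic part, component 2 the hydrogen-bond donor), their mole
  fractions, the temperature, two halide indicator flags and the observed
  property (e.g. density in g/cm3);
* a *component descriptor table* — one row per pure chemical, columns are
  named numeric molecular descriptors.

Mixture identity includes the molar ratio: the same chemical pair at 1:1
and 2:1 molar ratios counts as two distinct mixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column names of the mixture table
MIXTURE_COLUMNS = (
    "record_id",
    "comp1_id",
    "comp2_id",
    "x1",
    "x2",
    "T_K",
    "has_Cl",
    "has_Br",
    "y",
)

#: |x1 + x2 - 1| above this is a data error; below it the fractions are
#: renormalized to sum exactly to one.
MOLE_FRACTION_TOL = 1e-6


class SchemaError(ValueError):
    """A required column is missing or mis-mapped."""


class ReferenceError_(KeyError):
    """A chemical id in the mixture table is absent from the descriptor table."""


class ValidationError(ValueError):
    """A row violates a dataset invariant."""


@dataclass(frozen=True)
class MixtureRecord:
    """One experimental data point of a binary mixture."""

    record_id: str
    comp1_id: str
    comp2_id: str
    x1: float
    x2: float
    temperature_K: float
    has_chloride: int
    has_bromide: int
    y: float


@dataclass(frozen=True, order=True)
class MixtureKey:
    """Identity of a unique mixture: chemical pair plus molar-ratio signature.

    Two records with the same components and the same ratio signature
    belong to the same mixture regardless of temperature.
    """

    comp1_id: str
    comp2_id: str
    ratio_signature: str

    @staticmethod
    def from_fractions(
        comp1_id: str, comp2_id: str, x1: float, x2: float, precision: int = 4
    ) -> "MixtureKey":
        sig = f"{round(float(x1), precision):g}:{round(float(x2), precision):g}"
        return MixtureKey(comp1_id, comp2_id, sig)


class ComponentDescriptorTable:
    """Named descriptor vectors for pure chemicals.

    Wraps a DataFrame indexed by chemical id whose columns share one
    descriptor-name schema with no missing values.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate chemical ids: {dups}")
        if frame.isna().any().any():
            bad = frame.columns[frame.isna().any()].tolist()
            raise ValidationError(f"missing descriptor values in columns {bad}")
        self.frame = frame.astype(float)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.frame.columns)

    def vector(self, chemical_id: str) -> pd.Series:
        try:
            return self.frame.loc[chemical_id]
        except KeyError:
            raise ReferenceError_(f"unknown chemical id: {chemical_id!r}") from None

    def __contains__(self, chemical_id: str) -> bool:
        return chemical_id in self.frame.index

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class MixtureDataset:
    """Ordered mixture records plus the component descriptor table.

    ``records`` is a DataFrame with the canonical :data:`MIXTURE_COLUMNS`;
    row order is the file order and is stable across runs.
    """

    records: pd.DataFrame
    component_table: ComponentDescriptorTable
    ratio_precision: int = 4

    def __post_init__(self) -> None:
        missing = [c for c in MIXTURE_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"mixture table lacks columns {missing}")
        self.records = self.records.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        rec = self.records
        unknown = sorted(
            set(rec["comp1_id"]).union(rec["comp2_id"])
            - set(self.component_table.frame.index)
        )
        if unknown:
            raise ReferenceError_(
                f"chemical ids absent from descriptor table: {unknown}"
            )
        for i, row in rec.iterrows():
            s = row["x1"] + row["x2"]
            if row["x1"] < 0 or row["x2"] < 0 or abs(s - 1.0) > MOLE_FRACTION_TOL:
                raise ValidationError(
                    f"row {i} (record {row['record_id']!r}): mole fractions "
                    f"x1={row['x1']}, x2={row['x2']} do not sum to 1"
                )
            if row["T_K"] <= 0:
                raise ValidationError(f"row {i}: non-positive temperature {row['T_K']}")
            if row["y"] <= 0:
                raise ValidationError(f"row {i}: non-positive property value {row['y']}")
            if row["has_Cl"] not in (0, 1) or row["has_Br"] not in (0, 1):
                raise ValidationError(f"row {i}: halide flags must be 0 or 1")
        # halide flags are a property of component 1: at most one of the two
        # flags may be set, consistently across all records of that chemical
        for cid, grp in rec.groupby("comp1_id", sort=False):
            if grp[["has_Cl", "has_Br"]].nunique().max() > 1:
                raise ValidationError(
                    f"inconsistent halide flags for component-1 chemical {cid!r}"
                )
            if int(grp["has_Cl"].iloc[0]) + int(grp["has_Br"].iloc[0]) > 1:
                raise ValidationError(
                    f"component-1 chemical {cid!r} flagged as both chloride and bromide"
                )
        # renormalize tiny mole-fraction drift so x1 + x2 == 1 exactly
        s = rec["x1"] + rec["x2"]
        rec["x1"] = rec["x1"] / s
        rec["x2"] = rec["x2"] / s

    def __len__(self) -> int:
        return len(self.records)

    def iter_records(self) -> Iterator[MixtureRecord]:
        for _, row in self.records.iterrows():
            yield MixtureRecord(
                record_id=str(row["record_id"]),
                comp1_id=str(row["comp1_id"]),
                comp2_id=str(row["comp2_id"]),
                x1=float(row["x1"]),
                x2=float(row["x2"]),
                temperature_K=float(row["T_K"]),
                has_chloride=int(row["has_Cl"]),
                has_bromide=int(row["has_Br"]),
                y=float(row["y"]),
            )

    def mixture_keys(self) -> pd.Series:
        """Per-record :class:`MixtureKey`, aligned with ``records``."""
        keys = [
            MixtureKey.from_fractions(
                row["comp1_id"], row["comp2_id"], row["x1"], row["x2"],
                self.ratio_precision,
            )
            for _, row in self.records.iterrows()
        ]
        return pd.Series(keys, index=self.records.index, name="mixture_key")

    def subset(self, positions: Sequence[int]) -> "MixtureDataset":
        """New dataset restricted to the given positional indices (order kept)."""
        sub = self.records.iloc[list(positions)].reset_index(drop=True)
        return MixtureDataset(sub, self.component_table, self.ratio_precision)


def read_component_table(path: str | Path) -> ComponentDescriptorTable:
    """Read a component descriptor CSV (first column = chemical id)."""
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise SchemaError("descriptor table needs an id column plus >=1 descriptor")
    frame = frame.set_index(frame.columns[0])
    frame.index = frame.index.astype(str)
    return ComponentDescriptorTable(frame)


def read_mixture_table(
    path: str | Path,
    component_table: ComponentDescriptorTable,
    schema: Mapping[str, str] | None = None,
    ratio_precision: int = 4,
) -> MixtureDataset:
    """Read and validate a mixture CSV into a :class:`MixtureDataset`.

    Parameters
    ----------
    path:
        CSV file with one row per data point.
    component_table:
        Descriptor table every component id must resolve in.
    schema:
        Optional mapping from canonical field name (see
        :data:`MIXTURE_COLUMNS`) to the column name used in the file.
    ratio_precision:
        Decimals used when rounding mole fractions into the mixture key.
    """
    raw = pd.read_csv(path)
    schema = dict(schema or {})
    rename = {}
    missing = []
    for canon in MIXTURE_COLUMNS:
        src = schema.get(canon, canon)
        if src not in raw.columns:
            missing.append(src)
        else:
            rename[src] = canon
    if missing:
        raise SchemaError(f"mixture table {path} lacks columns {missing}")
    rec = raw.rename(columns=rename)[list(MIXTURE_COLUMNS)].copy()
    rec["record_id"] = rec["record_id"].astype(str)
    rec["comp1_id"] = rec["comp1_id"].astype(str)
    rec["comp2_id"] = rec["comp2_id"].astype(str)
    return MixtureDataset(rec, component_table, ratio_precision)


def write_mixture_table(
    dataset: MixtureDataset, path: str | Path, schema: Mapping[str, str] | None = None
) -> None:
    """Write the mixture table back to CSV (inverse of :func:`read_mixture_table`)."""
    out = dataset.records.copy()
    if schema:
        out = out.rename(columns=dict(schema))
    out.to_csv(path, index=False)


def write_component_table(table: ComponentDescriptorTable, path: str | Path) -> None:
    table.frame.rename_axis("chemical_id").to_csv(path)


def unique_mixtures(dataset: MixtureDataset) -> list[tuple[MixtureKey, int]]:
    """Unique mixtures with instance counts, sorted by count descending.

    Ties are broken by first occurrence in record order, so the result is
    deterministic for a given input file.
    """
    if len(dataset) == 0:
        raise ValidationError("empty dataset")
    keys = dataset.mixture_keys()
    counts: dict[MixtureKey, int] = {}
    first_seen: dict[MixtureKey, int] = {}
    for pos, key in enumerate(keys):
        counts[key] = counts.get(key, 0) + 1
        first_seen.setdefault(key, pos)
    ordered = sorted(counts, key=lambda k: (-counts[k], first_seen[k]))
    return [(k, counts[k]) for k in ordered]
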