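"""Dataset, split, and configuration file handling.

Datasets are header-bearing TSV/CSV files with columns ``id``, ``smiles``,
``endpoint`` (and an optional ``set`` column); split files are TSV/CSV
with columns ``id``, ``set``.  The delimiter is sniffed from the header
line.  The endpoint column is taken as final — any log transform (lnR,
pIC50, ...) is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["Dataset", "DataError", "read_dataset", "write_dataset",
           "read_split", "write_split", "read_config"]

TWO_SET = ("training", "validation")
THREE_SET = ("training", "calibration", "validation")


class DataError(ValueError):
    """Raised for malformed dataset/split/config files."""


@dataclass
class Dataset:
    """In-memory (id, smiles, endpoint) table."""

    ids: list[str]
    smiles: list[str]
    endpoints: np.ndarray
    sets: dict[str, str] = field(default_factory=dict)  # id -> set name

    def __post_init__(self) -> None:
        self.endpoints = np.asarray(self.endpoints, dtype=float)
        if not (len(self.ids) == len(self.smiles) == self.endpoints.size):
            raise DataError("ragged dataset columns")
        if len(set(self.ids)) != len(self.ids):
            raise DataError("duplicate ids in dataset")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, ids: Sequence[str]) -> "Dataset":
        index = {i: k for k, i in enumerate(self.ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise DataError(f"unknown ids: {missing[:5]}")
        rows = [index[i] for i in ids]
        return Dataset(
            [self.ids[r] for r in rows],
            [self.smiles[r] for r in rows],
            self.endpoints[rows],
        )

    def split(self, assignment: Mapping[str, str]) -> dict[str, "Dataset"]:
        """Partition by an id -> set-name assignment."""
        groups: dict[str, list[str]] = {}
        for mol_id in self.ids:
            name = assignment.get(mol_id)
            if name is None:
                raise DataError(f"id {mol_id!r} missing from split")
            groups.setdefault(name, []).append(mol_id)
        return {name: self.subset(ids) for name, ids in groups.items()}

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"id": self.ids, "smiles": self.smiles, "endpoint": self.endpoints}
        )
        if self.sets:
            df["set"] = [self.sets.get(i, "") for i in self.ids]
        return df

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, id_col="id", smiles_col="smiles", endpoint_col="endpoint"
    ) -> "Dataset":
        sets = {}
        if "set" in df.columns:
            sets = dict(zip(df[id_col].astype(str), df["set"].astype(str)))
        return cls(
            [str(v) for v in df[id_col]],
            [str(v).strip() for v in df[smiles_col]],
            df[endpoint_col].to_numpy(dtype=float),
            sets,
        )


def _sniff_sep(path: Path) -> str:
    header = path.read_text(encoding="utf-8").splitlines()[0]
    return "\t" if "\t" in header else ","


def read_dataset(path) -> Dataset:
    """Read and validate a dataset file; errors carry line numbers."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"id", "smiles", "endpoint"}
    if not required.issubset(df.columns):
        raise DataError(
            f"{path}: header must contain {sorted(required)}, got {list(df.columns)}"
        )
    dup = df["id"][df["id"].duplicated(keep=False)]
    if not dup.empty:
        lines = [int(i) + 2 for i in dup.index]  # +2: header + 1-based
        raise DataError(f"{path}: duplicate id {dup.iloc[0]!r} on lines {lines}")
    for idx, row in df.iterrows():
        line = int(idx) + 2
        smiles = str(row["smiles"]).strip()
        if not smiles or smiles.lower() == "nan":
            raise DataError(f"{path}:{line}: empty SMILES")
        try:
            value = float(row["endpoint"])
        except (TypeError, ValueError):
            raise DataError(
                f"{path}:{line}: unparseable endpoint {row['endpoint']!r}"
            ) from None
        if not np.isfinite(value):
            raise DataError(f"{path}:{line}: non-finite endpoint")
    df["smiles"] = df["smiles"].str.strip()
    return Dataset.from_dataframe(df)


def write_dataset(dataset: Dataset, path) -> None:
    dataset.to_dataframe().to_csv(path, sep="\t", index=False)


def read_split(path, dataset: Dataset | None = None) -> dict[str, str]:
    """Read an id -> set assignment; optionally validate against a dataset."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if not {"id", "set"}.issubset(df.columns):
        raise DataError(f"{path}: split header must contain ['id', 'set']")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise DataError(f"{path}: id {dup!r} assigned more than once")
    names = set(df["set"])
    if not (names <= set(TWO_SET) or names <= set(THREE_SET)):
        raise DataError(f"{path}: unknown set names {sorted(names)}")
    assignment = dict(zip(df["id"], df["set"]))
    if dataset is not None:
        ds_ids = set(dataset.ids)
        unknown = sorted(set(assignment) - ds_ids)
        if unknown:
            raise DataError(f"{path}: split ids not in dataset: {unknown[:5]}")
        missing = sorted(ds_ids - set(assignment))
        if missing:
            raise DataError(f"{path}: dataset ids missing from split: {missing[:5]}")
    return assignment


def write_split(assignment: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"id": list(assignment), "set": list(assignment.values())}
    ).to_csv(path, sep="\t", index=False)


def read_config(path) -> dict:
    """Read a TOML configuration file (threshold_T, epochs_N, families, ...)."""
    import tomllib

    with open(path, "rb") as fh:
        try:
            return tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise DataError(f"{path}: {exc}") from None
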