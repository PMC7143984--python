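"""Loaders for the bundled reference tables.

Three plain-text tables ship with the package under ``cwqsar/data``:

* ``endpoint_promoter_blocks.tsv`` — pairwise promoter-stability blocks
  for three biochemical endpoints (mutagenicity lnR, anticancer pIC50,
  blood-brain-barrier permeation), three optimization runs per endpoint.
* ``carcinogenicity_promoters.tsv`` — split × run promoter indicators for
  rat-carcinogenicity models fitted separately for male and female rats
  (three splits × three runs per cohort), with the published row totals.
* ``anticancer_splits.tsv`` — three published training/validation splits
  of an 87-compound anticancer-inhibitor series (compound indices only;
  the structures themselves are not distributed).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .similarity import ConsistencyTable, StabilityProfile

__all__ = [
    "load_promoter_blocks",
    "load_consistency_reference",
    "load_reference_splits",
]


def _data_path(name: str):
    return resources.files("cwqsar.data").joinpath(name)


def load_promoter_blocks() -> dict[tuple[str, str], tuple[StabilityProfile, StabilityProfile]]:
    """Pairwise stability-profile fixtures keyed by (endpoint_a, endpoint_b)."""
    with _data_path("endpoint_promoter_blocks.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    blocks: dict[tuple[str, str], tuple[StabilityProfile, StabilityProfile]] = {}
    for (ea, eb), grp in df.groupby(["endpoint_1", "endpoint_2"], sort=False):
        signs_a = {
            row["attribute"]: [row["e1_r1"], row["e1_r2"], row["e1_r3"]]
            for _, row in grp.iterrows()
        }
        signs_b = {
            row["attribute"]: [row["e2_r1"], row["e2_r2"], row["e2_r3"]]
            for _, row in grp.iterrows()
        }
        blocks[(ea, eb)] = (
            StabilityProfile.from_signs(ea, signs_a),
            StabilityProfile.from_signs(eb, signs_b),
        )
    return blocks


def load_consistency_reference() -> tuple[ConsistencyTable, pd.DataFrame]:
    """Reference split × run promoter table and its published row totals.

    Returns the :class:`ConsistencyTable` rebuilt from the 0/1 indicators
    and the raw frame (which carries the published ``total_mr`` /
    ``total_fr`` columns for cross-checking).
    """
    with _data_path("carcinogenicity_promoters.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    splits, runs = ("1", "2", "3"), ("1", "2", "3")
    columns = [(s, r) for s in splits for r in runs]
    cells = {}
    for cohort, prefix in (("mr", "mr"), ("fr", "fr")):
        mat = np.array(
            [
                [int(row[f"{prefix}_s{s}r{r}"]) for s, r in columns]
                for _, row in df.iterrows()
            ],
            dtype=int,
        )
        cells[cohort] = mat
    table = ConsistencyTable(
        attributes=list(df["attribute"]),
        cohorts=["mr", "fr"],
        columns=columns,
        cells=cells,
    )
    totals = df[["attribute", "source", "total_mr", "total_fr"]].copy()
    totals["total_mr"] = totals["total_mr"].astype(int)
    totals["total_fr"] = totals["total_fr"].astype(int)
    return table, totals


def load_reference_splits() -> dict[str, dict[str, str]]:
    """Published training/validation assignments, keyed by split id."""
    with _data_path("anticancer_splits.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    out: dict[str, dict[str, str]] = {}
    for split_id, grp in df.groupby("split", sort=False):
        out[str(split_id)] = dict(zip(grp["id"], grp["set"]))
    return out
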