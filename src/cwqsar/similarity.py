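"""Promoter stability across optimizer runs and endpoint similarity.

An attribute whose correlation weight is positive in *every* independent
optimization run for an endpoint is a stable promoter of endpoint
increase (+1); negative in every run, a stable promoter of decrease (−1);
anything else — a sign flip across runs, or a blocked attribute — is
unstable (0).  Two endpoints are similar in as many attributes as carry
the same non-zero label for both, and dissimilar in as many as carry
opposite non-zero labels.

The split × run consistency table is the related bookkeeping for one
endpoint modelled in several cohorts (e.g. male vs female animals): each
cell is 1 when the attribute's weight is positive in that (split, run)
model, and row totals count the cells per cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attributes import normalize_key
from .descriptor import CorrelationWeightTable

__all__ = [
    "StabilityProfile",
    "SimilarityMatrix",
    "ConsistencyTable",
    "classify_promoters",
    "compare_profiles",
    "similarity_matrix",
    "consistency_table",
    "render_report",
    "read_profile",
    "write_profile",
]


@dataclass
class StabilityProfile:
    """Per-attribute promoter labels (+1/−1/0) for one endpoint."""

    endpoint_id: str
    labels: dict[str, int]
    runs: int

    def __post_init__(self) -> None:
        if self.runs < 2:
            raise ValueError("stability needs at least 2 runs")
        bad = {k: v for k, v in self.labels.items() if v not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"labels must be -1/0/+1, got {bad}")

    @property
    def stable_count(self) -> int:
        return sum(1 for v in self.labels.values() if v != 0)

    @classmethod
    def from_signs(cls, endpoint_id: str, signs: Mapping[str, Sequence[str]]):
        """Build from per-run '+'/'−' marks, e.g. {"C...": ["+","+","+"]}."""
        labels = {}
        runs = None
        for key, marks in signs.items():
            runs = len(marks)
            if all(m == "+" for m in marks):
                labels[normalize_key(key)] = 1
            elif all(m in "-−" for m in marks):
                labels[normalize_key(key)] = -1
            else:
                labels[normalize_key(key)] = 0
        return cls(endpoint_id, labels, runs or 0)


def classify_promoters(
    runs: Sequence[CorrelationWeightTable], endpoint_id: str = ""
) -> StabilityProfile:
    """Label attributes by weight-sign stability across optimization runs."""
    if len(runs) < 2:
        raise ValueError("at least 2 runs required")
    universes = [set(t.weights) | set(t.blocked) for t in runs]
    shared = set.intersection(*universes)
    if not shared:
        raise ValueError("runs have disjoint attribute universes")
    all_keys = set.union(*universes)
    labels: dict[str, int] = {}
    for key in all_keys:
        blocked = any(key in t.blocked or key not in t.weights for t in runs)
        if blocked:
            labels[key] = 0
            continue
        ws = [t.weights[key] for t in runs]
        if all(w > 0 for w in ws):
            labels[key] = 1
        elif all(w < 0 for w in ws):
            labels[key] = -1
        else:
            labels[key] = 0
    return StabilityProfile(endpoint_id, labels, len(runs))


def compare_profiles(
    a: StabilityProfile, b: StabilityProfile
) -> tuple[int, int]:
    """(similarity, dissimilarity) counts over the union of attributes.

    Similarity counts attributes with identical non-zero labels;
    dissimilarity counts opposite non-zero labels.  Missing keys count
    as unstable (0).  Symmetric in its arguments.
    """
    keys = set(a.labels) | set(b.labels)
    sim = dis = 0
    for key in keys:
        la = a.labels.get(key, 0)
        lb = b.labels.get(key, 0)
        if la == 0 or lb == 0:
            continue
        if la == lb:
            sim += 1
        else:
            dis += 1
    return sim, dis


@dataclass
class SimilarityMatrix:
    """Pairwise endpoint similarity/dissimilarity counts.

    The similarity diagonal holds each endpoint's stable-attribute count;
    the dissimilarity diagonal is 0 by construction.
    """

    endpoints: list[str]
    similarity: np.ndarray
    dissimilarity: np.ndarray

    def to_dataframes(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return (
            pd.DataFrame(self.similarity, index=self.endpoints, columns=self.endpoints),
            pd.DataFrame(
                self.dissimilarity, index=self.endpoints, columns=self.endpoints
            ),
        )

    @classmethod
    def from_profiles(cls, profiles: Sequence[StabilityProfile]) -> "SimilarityMatrix":
        return similarity_matrix(profiles)

    @classmethod
    def from_profile_pairs(
        cls,
        endpoints: Sequence[str],
        pairs: Mapping[tuple[str, str], tuple[StabilityProfile, StabilityProfile]],
    ) -> "SimilarityMatrix":
        """Assemble from per-pair profile fixtures (one block per pair).

        Used when each endpoint pair was profiled jointly (a shared
        curated attribute list per pair), so no single profile spans all
        pairs.  Diagonals are left at 0.
        """
        n = len(endpoints)
        sim = np.zeros((n, n), dtype=int)
        dis = np.zeros((n, n), dtype=int)
        index = {e: i for i, e in enumerate(endpoints)}
        for (ea, eb), (pa, pb) in pairs.items():
            s, d = compare_profiles(pa, pb)
            i, j = index[ea], index[eb]
            sim[i, j] = sim[j, i] = s
            dis[i, j] = dis[j, i] = d
        return cls(list(endpoints), sim, dis)


def similarity_matrix(profiles: Sequence[StabilityProfile]) -> SimilarityMatrix:
    """Pairwise comparison of a list of stability profiles."""
    if len(profiles) < 2:
        raise ValueError("at least 2 profiles required")
    n = len(profiles)
    sim = np.zeros((n, n), dtype=int)
    dis = np.zeros((n, n), dtype=int)
    for i in range(n):
        sim[i, i] = profiles[i].stable_count
        for j in range(i + 1, n):
            s, d = compare_profiles(profiles[i], profiles[j])
            sim[i, j] = sim[j, i] = s
            dis[i, j] = dis[j, i] = d
    return SimilarityMatrix([p.endpoint_id for p in profiles], sim, dis)


@dataclass
class ConsistencyTable:
    """Split × run promoter indicators per cohort, with row totals."""

    attributes: list[str]
    cohorts: list[str]
    columns: list[tuple[str, str]]  # (split, run) design, shared by cohorts
    cells: dict[str, np.ndarray] = field(default_factory=dict)  # cohort -> matrix

    def row_totals(self, cohort: str) -> np.ndarray:
        return self.cells[cohort].sum(axis=1)

    def grand_total(self, cohort: str) -> int:
        return int(self.cells[cohort].sum())

    def to_dataframe(self) -> pd.DataFrame:
        frames = {}
        for cohort in self.cohorts:
            df = pd.DataFrame(
                self.cells[cohort],
                index=self.attributes,
                columns=[f"{s}.{r}" for s, r in self.columns],
            )
            df[f"total_{cohort}"] = self.row_totals(cohort)
            frames[cohort] = df
        return pd.concat(frames, axis=1)


def consistency_table(
    models: Mapping[str, Mapping[tuple[str, str], CorrelationWeightTable]],
    attributes: Sequence[str] | None = None,
) -> ConsistencyTable:
    """Build the promoter-consistency table from per-cohort model grids.

    ``models`` maps cohort -> {(split, run) -> weight table}; the design
    must be rectangular (identical (split, run) cells in every cohort).
    A cell indicator is 1 iff the attribute's weight is strictly positive
    in that model.
    """
    cohorts = list(models)
    if not cohorts:
        raise ValueError("no cohorts supplied")
    designs = [sorted(models[c]) for c in cohorts]
    if any(d != designs[0] for d in designs[1:]):
        missing = {
            c: sorted(set(designs[0]) ^ set(sorted(models[c]))) for c in cohorts
        }
        raise ValueError(f"non-rectangular design; mismatched cells: {missing}")
    columns = designs[0]
    if attributes is None:
        keys: set[str] = set()
        for c in cohorts:
            for table in models[c].values():
                keys |= set(table.weights)
        attributes = sorted(keys)
    attributes = list(attributes)
    cells = {}
    for c in cohorts:
        mat = np.zeros((len(attributes), len(columns)), dtype=int)
        for j, cell in enumerate(columns):
            table = models[c][cell]
            for i, key in enumerate(attributes):
                mat[i, j] = 1 if table.weights.get(key, 0.0) > 0 else 0
        cells[c] = mat
    return ConsistencyTable(attributes, cohorts, columns, cells)


def render_report(a: StabilityProfile, b: StabilityProfile) -> str:
    """Text block comparing two profiles: agreements first, then conflicts."""
    keys = sorted(set(a.labels) | set(b.labels))
    mark = {1: "+", -1: "-", 0: "."}

    def row(key: str) -> str:
        la, lb = a.labels.get(key, 0), b.labels.get(key, 0)
        cols = [mark[la]] * a.runs + [mark[lb]] * b.runs
        return key + "\t" + "\t".join(cols)

    agree = [k for k in keys
             if a.labels.get(k, 0) == b.labels.get(k, 0) != 0]
    conflict = [k for k in keys
                if 0 != a.labels.get(k, 0) == -b.labels.get(k, 0)]
    header = (
        f"# {a.endpoint_id} (#1) vs {b.endpoint_id} (#2)\n"
        "attribute\t"
        + "\t".join(f"m1.{i+1}" for i in range(a.runs))
        + "\t"
        + "\t".join(f"m2.{i+1}" for i in range(b.runs))
    )
    lines = [header]
    lines += [row(k) for k in agree]
    lines += [row(k) for k in conflict]
    return "\n".join(lines) + "\n"


def write_profile(
    tables: Sequence[CorrelationWeightTable], path, endpoint_id: str = ""
) -> None:
    """Profile interchange TSV: attribute key, then one CW column per run."""
    keys = sorted(set().union(*(set(t.weights) | set(t.blocked) for t in tables)))
    with open(path, "w", encoding="utf-8") as fh:
        header = ["attribute"] + [f"run{i+1}" for i in range(len(tables))]
        fh.write("# endpoint: " + endpoint_id + "\n")
        fh.write("\t".join(header) + "\n")
        for key in keys:
            row = [key] + [repr(t.weights.get(key, 0.0)) for t in tables]
            fh.write("\t".join(row) + "\n")


def read_profile(path) -> tuple[str, list[CorrelationWeightTable]]:
    """Read a profile interchange TSV written by :func:`write_profile`."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    endpoint_id = ""
    if lines and lines[0].startswith("# endpoint:"):
        endpoint_id = lines.pop(0).split(":", 1)[1].strip()
    header = lines.pop(0).split("\t")
    n_runs = len(header) - 1
    tables = [CorrelationWeightTable() for _ in range(n_runs)]
    for ln in lines:
        parts = ln.split("\t")
        key = normalize_key(parts[0])
        for t, val in zip(tables, parts[1:]):
            t.weights[key] = float(val)
    return endpoint_id, tables
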