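"""Correlation-weight descriptor DCW(T, N) and the one-variable calibration.

The descriptor value of a molecule is the sum, over all attribute
instances it contains (respecting multiplicity), of per-attribute real
correlation weights:

    DCW(T, N) = sum_k CW(A_k)

Attributes occurring in fewer than T distinct training molecules are
*blocked*: their weight is fixed at 0 and they never enter the sum.  The
endpoint model is the one-variable line

    endpoint = C0 + C1 * DCW,

with C0/C1 from ordinary least squares on the training set.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .attributes import DescriptorConfig, extract_attributes

__all__ = [
    "CorrelationWeightTable",
    "LinearCalibration",
    "QsarModel",
    "active_attributes",
    "dcw",
    "calibrate",
    "DegenerateModelError",
]

logger = logging.getLogger(__name__)


class DegenerateModelError(ValueError):
    """Raised when the descriptor has zero variance over the training set."""


@dataclass
class CorrelationWeightTable:
    """Attribute key -> correlation weight, plus the blocked-key set.

    Blocked keys carry weight exactly 0.  Keys absent from both maps are
    out of vocabulary: they contribute 0 to DCW and are counted in
    ``oov_seen`` as a crude applicability-domain signal.
    """

    weights: dict[str, float] = field(default_factory=dict)
    blocked: set[str] = field(default_factory=set)
    oov_seen: int = 0

    def __post_init__(self) -> None:
        for key in self.blocked:
            if self.weights.get(key, 0.0) != 0.0:
                raise ValueError(f"blocked key {key!r} has non-zero weight")

    def weight(self, key: str) -> float:
        return self.weights.get(key, 0.0)

    def dcw(self, attrs: Mapping[str, int]) -> float:
        """Descriptor value of one attribute multiset."""
        total = 0.0
        for key, mult in attrs.items():
            if key in self.weights:
                total += self.weights[key] * mult
            elif key not in self.blocked:
                self.oov_seen += 1
                logger.debug("out-of-vocabulary attribute %r (contributes 0)", key)
        return total

    def copy(self) -> "CorrelationWeightTable":
        return CorrelationWeightTable(dict(self.weights), set(self.blocked))


def dcw(attrs: Mapping[str, int], cw: CorrelationWeightTable) -> float:
    """Functional form of :meth:`CorrelationWeightTable.dcw`."""
    return cw.dcw(attrs)


def active_attributes(
    molecule_attrs: Sequence[Mapping[str, int]], threshold: int
) -> tuple[set[str], set[str]]:
    """Split the attribute universe into (active, blocked) at threshold T.

    A key is active when it occurs in at least T *distinct* molecules of
    the training set; everything else observed is blocked.
    """
    if threshold < 1:
        raise ValueError("threshold T must be >= 1")
    presence: Counter[str] = Counter()
    for attrs in molecule_attrs:
        presence.update(set(attrs))
    active = {k for k, c in presence.items() if c >= threshold}
    blocked = set(presence) - active
    return active, blocked


@dataclass(frozen=True)
class LinearCalibration:
    """One-variable line endpoint = c0 + c1 * DCW (endpoint units)."""

    c0: float
    c1: float

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.c0 + self.c1 * np.asarray(x, dtype=float)


def calibrate(
    dcw_values: Sequence[float], endpoints: Sequence[float]
) -> LinearCalibration:
    """Ordinary least squares fit of the one-variable line."""
    x = np.asarray(dcw_values, dtype=float)
    y = np.asarray(endpoints, dtype=float)
    if x.size != y.size:
        raise ValueError("dcw_values and endpoints differ in length")
    if x.size < 3:
        raise ValueError("calibration needs at least 3 points")
    if np.ptp(x) == 0.0:
        raise DegenerateModelError("descriptor has zero variance")
    c1, c0 = np.polyfit(x, y, 1)
    return LinearCalibration(float(c0), float(c1))


@dataclass
class QsarModel:
    """A fitted correlation-weight QSAR model (fully self-describing).

    Predictions depend only on the stored fields, so a saved model file
    reproduces predictions bit for bit.
    """

    config: DescriptorConfig
    cw: CorrelationWeightTable
    calibration: LinearCalibration
    seed: int = 0
    split_id: str = ""

    def descriptor(self, smiles: str) -> float:
        return self.cw.dcw(extract_attributes(smiles, self.config))

    def predict(self, smiles: str) -> float:
        return float(self.calibration(self.descriptor(smiles)))

    def predict_many(self, smiles_list: Iterable[str]) -> np.ndarray:
        return np.array([self.predict(s) for s in smiles_list])

    # -- persistence ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "cwqsar-model",
            "version": 1,
            "seed": self.seed,
            "split_id": self.split_id,
            "config": {
                "threshold": self.config.threshold,
                "epochs": self.config.epochs,
                "families": sorted(self.config.families),
            },
            "calibration": {"c0": self.calibration.c0, "c1": self.calibration.c1},
            "blocked": sorted(self.cw.blocked),
            # repr round-trips IEEE doubles exactly (17 significant digits)
            "weights": {k: float(v) for k, v in sorted(self.cw.weights.items())},
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=False)
            fh.write("\n")

    @classmethod
    def from_dict(cls, doc: dict) -> "QsarModel":
        if doc.get("format") != "cwqsar-model":
            raise ValueError("not a cwqsar model document")
        cfg = DescriptorConfig(
            threshold=doc["config"]["threshold"],
            epochs=doc["config"]["epochs"],
            families=frozenset(doc["config"]["families"]),
        )
        cw = CorrelationWeightTable(
            {k: float(v) for k, v in doc["weights"].items()},
            set(doc["blocked"]),
        )
        cal = LinearCalibration(
            float(doc["calibration"]["c0"]), float(doc["calibration"]["c1"])
        )
        return cls(cfg, cw, cal, seed=int(doc["seed"]), split_id=doc["split_id"])

    @classmethod
    def load(cls, path) -> "QsarModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
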