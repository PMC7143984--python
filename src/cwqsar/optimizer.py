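"""Seeded coordinate-wise Monte Carlo optimization of correlation weights.

Each epoch visits every active attribute once, in a freshly shuffled
order, and proposes a perturbation CW' = CW +/- u with
u ~ Uniform(0, step_max]; the drawn magnitude is tried in one random
direction first and, if that does not improve the target, in the
opposite direction.  A move is kept only if the training target strictly
increases (greedy acceptance, no temperature), so the per-epoch trace of
the target is non-decreasing.  All randomness comes from one numpy
Generator seeded per run; identical inputs and seed give bit-identical
weight tables.

The default target is the *magnitude* of the Pearson correlation between
the descriptor DCW and the endpoint over the training set: the sign of
the association is absorbed by the calibration slope C1, so |r| is the
quantity a one-variable model should maximize (signed r would have to
fight its way through r = 0 whenever the initial descriptor happens to
anti-correlate).  The "balance" target mixes a training subset and a
calibration subset: r_sub + r_cal - 0.1 * |r_sub - r_cal|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .attributes import DescriptorConfig, extract_attributes
from .descriptor import (
    CorrelationWeightTable,
    LinearCalibration,
    QsarModel,
    active_attributes,
    calibrate,
)
from .io import Dataset

__all__ = ["OptimizerConfig", "RunResult", "target_function", "optimize", "run_ensemble"]


@dataclass(frozen=True)
class OptimizerConfig:
    """Monte Carlo search settings.

    ``step_max`` is the largest proposal magnitude per move; ``init_mode``
    is "ones" (all weights start at 1.0) or "uniform" (uniform(-1, 1)
    draws, useful for run-ensemble stability analysis); ``target`` is
    "r_train" or "balance"; ``early_stop_tol`` > 0 stops when an epoch
    improves the target by less than the tolerance.
    """

    seed: int = 0
    epochs: int | None = None  # None: take N from the DescriptorConfig
    step_max: float = 0.1
    init_mode: str = "ones"
    target: str = "r_train"
    early_stop_tol: float = 0.0

    def __post_init__(self) -> None:
        if self.step_max <= 0:
            raise ValueError("step_max must be positive")
        if self.init_mode not in ("ones", "uniform"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.target not in ("r_train", "balance"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.early_stop_tol < 0:
            raise ValueError("early_stop_tol must be >= 0")


@dataclass
class RunResult:
    """One optimization run: the fitted model, its trace, and move count."""

    model: QsarModel
    trace: list[float] = field(default_factory=list)
    accepted_moves: int = 0


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, with -1 as the degenerate-variance sentinel."""
    if x.size < 2 or np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return -1.0
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def _abs_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """|Pearson r|, keeping the -1 degenerate sentinel."""
    r = _pearson(x, y)
    return r if r == -1.0 else abs(r)


def target_function(
    cw: CorrelationWeightTable,
    training: Dataset,
    config: DescriptorConfig | None = None,
) -> float:
    """Training target of a weight table: |Pearson r(DCW, endpoint)|.

    Returns -1 when the descriptor is degenerate (zero variance).
    """
    if len(training) == 0:
        raise ValueError("empty training set")
    if config is None:
        config = DescriptorConfig()
    x = np.array(
        [cw.dcw(extract_attributes(s, config)) for s in training.smiles]
    )
    return _abs_pearson(x, training.endpoints)


def _balance_value(
    x_sub: np.ndarray, y_sub: np.ndarray, x_cal: np.ndarray, y_cal: np.ndarray
) -> float:
    r_sub = _abs_pearson(x_sub, y_sub)
    r_cal = _abs_pearson(x_cal, y_cal)
    return r_sub + r_cal - 0.1 * abs(r_sub - r_cal)


def optimize(
    training: Dataset,
    dconf: DescriptorConfig | None = None,
    oconf: OptimizerConfig | None = None,
    calibration_set: Dataset | None = None,
    split_id: str = "",
) -> RunResult:
    """Run one Monte Carlo optimization and calibrate the final model.

    With ``epochs == 0`` the weights stay at their initialization and only
    the OLS calibration is performed.  Fully reproducible from
    (training data, dconf, oconf).
    """
    dconf = dconf or DescriptorConfig()
    oconf = oconf or OptimizerConfig()
    if oconf.target == "balance" and calibration_set is None:
        raise ValueError("balance target requires a calibration set")
    epochs = dconf.epochs if oconf.epochs is None else oconf.epochs

    mol_attrs = [extract_attributes(s, dconf) for s in training.smiles]
    active, blocked = active_attributes(mol_attrs, dconf.threshold)
    if not active:
        raise ValueError(
            f"all attributes blocked at threshold T={dconf.threshold}"
        )
    keys = sorted(active)
    n_train = len(training)
    # incidence columns: multiplicity of each active attribute per molecule
    columns = {
        k: np.array([attrs.get(k, 0) for attrs in mol_attrs], dtype=float)
        for k in keys
    }

    rng = np.random.default_rng(oconf.seed)
    if oconf.init_mode == "ones":
        weights = {k: 1.0 for k in keys}
    else:
        weights = {k: float(w) for k, w in zip(keys, rng.uniform(-1, 1, len(keys)))}

    y = training.endpoints
    x = np.zeros(n_train)
    for k in keys:
        x += weights[k] * columns[k]

    if oconf.target == "balance":
        assert calibration_set is not None
        cal_attrs = [extract_attributes(s, dconf) for s in calibration_set.smiles]
        cal_columns = {
            k: np.array([a.get(k, 0) for a in cal_attrs], dtype=float) for k in keys
        }
        y_cal = calibration_set.endpoints
        x_cal = np.zeros(len(calibration_set))
        for k in keys:
            x_cal += weights[k] * cal_columns[k]

        def value(xt: np.ndarray, xc: np.ndarray) -> float:
            return _balance_value(xt, y, xc, y_cal)

    accepted = 0
    if oconf.target == "balance":
        current = value(x, x_cal)
    else:
        current = _abs_pearson(x, y)
    trace: list[float] = []
    for _ in range(epochs):
        epoch_start = current
        order = rng.permutation(len(keys))
        for idx in order:
            key = keys[idx]
            u = rng.uniform(0.0, oconf.step_max)
            first = 1.0 if rng.random() < 0.5 else -1.0
            for sign in (first, -first):
                delta = sign * u
                x_new = x + delta * columns[key]
                if oconf.target == "balance":
                    x_cal_new = x_cal + delta * cal_columns[key]
                    cand = value(x_new, x_cal_new)
                else:
                    cand = _abs_pearson(x_new, y)
                if cand > current:
                    current = cand
                    x = x_new
                    if oconf.target == "balance":
                        x_cal = x_cal_new
                    weights[key] += delta
                    accepted += 1
                    break
        trace.append(current)
        if oconf.early_stop_tol > 0 and (current - epoch_start) < oconf.early_stop_tol:
            break

    # canonical orientation: DCW correlates positively with the endpoint,
    # so a positive weight always marks a promoter of endpoint increase
    # and the calibration slope is non-negative.
    if _pearson(x, y) < 0:
        weights = {k: -w for k, w in weights.items()}
        x = -x

    table = CorrelationWeightTable(dict(weights), set(blocked))
    try:
        cal = calibrate(x, y)
    except Exception:
        # degenerate descriptor: fall back to the endpoint mean
        cal = LinearCalibration(float(np.mean(y)), 0.0)
    model = QsarModel(dconf, table, cal, seed=oconf.seed, split_id=split_id)
    return RunResult(model=model, trace=trace, accepted_moves=accepted)


def run_ensemble(
    training: Dataset,
    dconf: DescriptorConfig | None = None,
    oconf: OptimizerConfig | None = None,
    seeds: Sequence[int] = (1, 2, 3),
    calibration_set: Dataset | None = None,
    split_id: str = "",
) -> list[RunResult]:
    """Independent optimization runs differing only in seed.

    Result order matches ``seeds``; duplicate seeds produce identical
    models and trigger a warning.
    """
    if len(seeds) == 0:
        raise ValueError("at least one seed required")
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds in ensemble", stacklevel=2)
    oconf = oconf or OptimizerConfig()
    return [
        optimize(
            training,
            dconf,
            replace(oconf, seed=int(s)),
            calibration_set=calibration_set,
            split_id=split_id,
        )
        for s in seeds
    ]
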