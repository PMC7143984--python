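"""Model/Results interface over the correlation-weight QSAR machinery.

`CorrelationWeightQsar` is constructed from data (arrays or a DataFrame),
holds the descriptor configuration, and `fit()` runs the Monte Carlo
search plus the OLS calibration, returning a `CorrelationWeightResults`
object that carries the weight table, the calibration line, the training
trace, prediction and validation methods, and a `summary()` table.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .attributes import DescriptorConfig
from .io import Dataset
from .optimizer import OptimizerConfig, RunResult, optimize, run_ensemble
from .stats import CriteriaReport, TrainingContext, full_report, loo_q2

__all__ = ["CorrelationWeightQsar", "CorrelationWeightResults"]


class CorrelationWeightQsar:
    """One-variable QSAR model: endpoint = C0 + C1 · DCW(T, N).

    Parameters
    ----------
    training : Dataset
        Training molecules and endpoint values.
    config : DescriptorConfig, optional
        Rarity threshold T, epoch count N and attribute families.
    calibration : Dataset, optional
        Calibration subset for the "balance" optimization target.
    split_id : str
        Free-text identifier of the split that produced the training set,
        stored in fitted models for provenance.
    """

    def __init__(
        self,
        training: Dataset,
        config: Optional[DescriptorConfig] = None,
        calibration: Optional[Dataset] = None,
        split_id: str = "",
    ) -> None:
        self.training = training
        self.config = config or DescriptorConfig()
        self.calibration = calibration
        self.split_id = split_id

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        config: Optional[DescriptorConfig] = None,
        id_col: str = "id",
        smiles_col: str = "smiles",
        endpoint_col: str = "endpoint",
        split_id: str = "",
    ) -> "CorrelationWeightQsar":
        return cls(
            Dataset.from_dataframe(df, id_col, smiles_col, endpoint_col),
            config=config,
            split_id=split_id,
        )

    def fit(
        self, seed: int = 0, optimizer: Optional[OptimizerConfig] = None
    ) -> "CorrelationWeightResults":
        """Run the Monte Carlo search and OLS calibration.

        ``seed`` always wins over ``optimizer.seed``.
        """
        from dataclasses import replace

        oconf = (
            replace(optimizer, seed=seed) if optimizer else OptimizerConfig(seed=seed)
        )
        run = optimize(
            self.training,
            self.config,
            oconf,
            calibration_set=self.calibration,
            split_id=self.split_id,
        )
        return CorrelationWeightResults(self, run)

    def fit_ensemble(
        self, seeds: Sequence[int], optimizer: Optional[OptimizerConfig] = None
    ) -> list["CorrelationWeightResults"]:
        runs = run_ensemble(
            self.training,
            self.config,
            optimizer,
            seeds=seeds,
            calibration_set=self.calibration,
            split_id=self.split_id,
        )
        return [CorrelationWeightResults(self, r) for r in runs]


class CorrelationWeightResults:
    """Fit results: weights, calibration, trace, diagnostics."""

    def __init__(self, model: CorrelationWeightQsar, run: RunResult) -> None:
        self.model = model
        self.run = run
        self.qsar = run.model

    # -- estimates -----------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {"c0": self.qsar.calibration.c0, "c1": self.qsar.calibration.c1}
        )

    @property
    def weights(self):
        return self.qsar.cw

    @property
    def trace(self) -> list[float]:
        return self.run.trace

    @property
    def seed(self) -> int:
        return self.qsar.seed

    def fittedvalues(self) -> np.ndarray:
        return self.qsar.predict_many(self.model.training.smiles)

    @property
    def rsquared_train(self) -> float:
        y = self.model.training.endpoints
        yhat = self.fittedvalues()
        ss_res = float(((y - yhat) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        return 1.0 - ss_res / ss_tot

    # -- application ---------------------------------------------------
    def predict(self, smiles) -> np.ndarray | float:
        if isinstance(smiles, str):
            return self.qsar.predict(smiles)
        return self.qsar.predict_many(smiles)

    def training_context(self) -> TrainingContext:
        return TrainingContext.from_endpoints(self.model.training.endpoints)

    def evaluate(self, dataset: Dataset, **kwargs) -> CriteriaReport:
        """Criteria report of this model on an external dataset."""
        predicted = self.qsar.predict_many(dataset.smiles)
        return full_report(
            dataset.endpoints, predicted, ctx=self.training_context(), **kwargs
        )

    def loo_q2_train(self) -> float:
        x = np.array([self.qsar.descriptor(s) for s in self.model.training.smiles])
        return loo_q2(x, self.model.training.endpoints)

    def save(self, path) -> None:
        self.qsar.save(path)

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        cfg = self.qsar.config
        lines = [
            "Correlation-weight QSAR results",
            "=" * 46,
            f"descriptor             DCW(T={cfg.threshold}, N={cfg.epochs})",
            f"families               {', '.join(sorted(cfg.families))}",
            f"training molecules     {len(self.model.training)}",
            f"active attributes      {len(self.qsar.cw.weights)}",
            f"blocked attributes     {len(self.qsar.cw.blocked)}",
            f"seed                   {self.seed}",
            f"split id               {self.qsar.split_id or '-'}",
            "-" * 46,
            f"C0 (intercept)         {self.qsar.calibration.c0: .6f}",
            f"C1 (slope)             {self.qsar.calibration.c1: .6f}",
            f"training r^2           {self.rsquared_train: .4f}",
            f"accepted MC moves      {self.run.accepted_moves}",
            f"final target value     {self.trace[-1] if self.trace else float('nan'): .6f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<CorrelationWeightResults seed={self.seed} "
            f"r2_train={self.rsquared_train:.3f}>"
        )
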