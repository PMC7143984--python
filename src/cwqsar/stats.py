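"""External-validation criteria for one-variable QSAR models.

Implements the standard battery of predictive-potential statistics used
to judge an (observed, predicted) pairing: Pearson r and r², Lin's
concordance correlation coefficient (CCC), the through-origin slopes and
determination coefficients of the Golbraikh–Tropsha checks (k, k', r0²,
r0'²), the external predictivity family Q²/Q²F1/Q²F2/Q²F3, Roy's rm²
metrics, and the index of ideality of correlation (IIC).

Conventions:

* x denotes observed values, y (or y~) predicted values, following the
  symbols used in the QSAR validation literature.
* Statistics that are undefined for a given input (zero variance, empty
  residual class where noted) raise :class:`UndefinedStatisticError`;
  :func:`full_report` converts those into absent (None) entries rather
  than silent zeros.  The one deliberate exception is the IIC, which is
  defined as 0 when all residuals share one sign.
* rm² is computed by default with the square-root form
  r²(1 − sqrt|r² − r0²|); ``sqrt_form=False`` selects the literal
  no-square-root variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "UndefinedStatisticError",
    "TrainingContext",
    "CriteriaReport",
    "pearson_r",
    "ccc",
    "through_origin",
    "q2_family",
    "loo_q2",
    "rm2_metrics",
    "iic",
    "golbraikh_tropsha",
    "full_report",
]


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for this input (e.g. zero variance)."""


@dataclass(frozen=True)
class TrainingContext:
    """Training-set summary needed by the Q²F1/F3 formulas.

    ``variance`` is the population variance of the training endpoints,
    i.e. sum((y - mean)²) / n_training.
    """

    mean: float
    n: int
    variance: float

    @classmethod
    def from_endpoints(cls, endpoints: Sequence[float]) -> "TrainingContext":
        y = np.asarray(endpoints, dtype=float)
        if y.size < 1:
            raise ValueError("empty training endpoints")
        return cls(float(y.mean()), int(y.size), float(y.var()))


def _pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    return x, y


def pearson_r(observed, predicted) -> float:
    """Product-moment correlation between observed and predicted values."""
    x, y = _pair(observed, predicted)
    if x.size < 3:
        raise UndefinedStatisticError("need at least 3 points")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedStatisticError("zero variance")
    xc, yc = x - x.mean(), y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def ccc(observed, predicted) -> float:
    """Lin's concordance correlation coefficient.

    2*sum((x-x̄)(y-ȳ)) / (sum((x-x̄)²) + sum((y-ȳ)²) + n(x̄-ȳ)²); the
    n(x̄-ȳ)² term penalizes location shift, so |CCC| <= |r| always.
    """
    x, y = _pair(observed, predicted)
    if x.size < 3:
        raise UndefinedStatisticError("need at least 3 points")
    xc, yc = x - x.mean(), y - y.mean()
    denom = xc @ xc + yc @ yc + x.size * (x.mean() - y.mean()) ** 2
    if denom == 0.0:
        raise UndefinedStatisticError("both variances zero")
    return float(2.0 * (xc @ yc) / denom)


def through_origin(observed, predicted) -> tuple[float, float, float, float]:
    """Golbraikh–Tropsha through-origin quantities (k, k', r0², r0'²).

    k = sum(y·y~)/sum(y~²) is the slope of the through-origin regression
    of observed on predicted, k' = sum(y·y~)/sum(y²) the reverse slope.
    r0² measures how well the through-origin line k'·y reproduces the
    predictions; r0'² how well k·y~ reproduces the observations.
    """
    y, yt = _pair(observed, predicted)  # y: observed, yt: predicted
    s_yyt = float(y @ yt)
    s_yt2 = float(yt @ yt)
    s_y2 = float(y @ y)
    if s_yt2 == 0.0 or s_y2 == 0.0:
        raise UndefinedStatisticError("zero through-origin denominator")
    k = s_yyt / s_yt2
    k_prime = s_yyt / s_y2
    d_yt = float(((yt - yt.mean()) ** 2).sum())
    d_y = float(((y - y.mean()) ** 2).sum())
    if d_yt == 0.0 or d_y == 0.0:
        raise UndefinedStatisticError("zero variance")
    r0_sq = 1.0 - float(((yt - k_prime * y) ** 2).sum()) / d_yt
    r0_sq_primed = 1.0 - float(((y - k * yt) ** 2).sum()) / d_y
    return k, k_prime, r0_sq, r0_sq_primed


def q2_family(
    observed, predicted, ctx: Optional[TrainingContext] = None
) -> tuple[float, Optional[float], float, Optional[float]]:
    """External predictivity family (Q², Q²F1, Q²F2, Q²F3).

    Q² and Q²F2 reference the external-set mean; Q²F1 references the
    training mean and Q²F3 normalizes the external PRESS per compound by
    the training-set endpoint variance.  F1 and F3 are None without a
    training context.
    """
    y, yhat = _pair(observed, predicted)
    if y.size < 3:
        raise UndefinedStatisticError("need at least 3 points")
    press = float(((y - yhat) ** 2).sum())
    ss_ext = float(((y - y.mean()) ** 2).sum())
    if ss_ext == 0.0:
        raise UndefinedStatisticError("zero external variance")
    q2 = 1.0 - press / ss_ext
    q2_f2 = q2
    q2_f1 = q2_f3 = None
    if ctx is not None:
        ss_tr = float(((y - ctx.mean) ** 2).sum())
        if ss_tr == 0.0:
            raise UndefinedStatisticError("zero deviation from training mean")
        q2_f1 = 1.0 - press / ss_tr
        if ctx.variance == 0.0:
            raise UndefinedStatisticError("zero training variance")
        q2_f3 = 1.0 - (press / y.size) / ctx.variance
    return q2, q2_f1, q2_f2, q2_f3


def loo_q2(x, y) -> float:
    """Leave-one-out Q² of the one-variable OLS line y ~ c0 + c1·x.

    Uses the closed-form PRESS of linear regression (residual / (1 - h)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise UndefinedStatisticError("need at least 4 points for LOO")
    if np.ptp(x) == 0.0:
        raise UndefinedStatisticError("zero descriptor variance")
    xc = x - x.mean()
    c1 = float(xc @ (y - y.mean()) / (xc @ xc))
    c0 = float(y.mean() - c1 * x.mean())
    resid = y - (c0 + c1 * x)
    h = 1.0 / x.size + xc**2 / (xc @ xc)
    press = float(((resid / (1.0 - h)) ** 2).sum())
    ss = float(((y - y.mean()) ** 2).sum())
    if ss == 0.0:
        raise UndefinedStatisticError("zero endpoint variance")
    return 1.0 - press / ss


def _rm2_one_direction(observed, predicted, sqrt_form: bool) -> float:
    r = pearson_r(observed, predicted)
    _, _, r0_sq, _ = through_origin(observed, predicted)
    gap = abs(r**2 - r0_sq)
    if sqrt_form:
        gap = np.sqrt(gap)
    return float(r**2 * (1.0 - gap))


def rm2_metrics(observed, predicted, sqrt_form: bool = True) -> tuple[float, float]:
    """Roy's rm² metrics: (average over both directions, absolute gap)."""
    fwd = _rm2_one_direction(observed, predicted, sqrt_form)
    rev = _rm2_one_direction(predicted, observed, sqrt_form)
    return (fwd + rev) / 2.0, abs(fwd - rev)


def iic(observed, calculated, r_calibration: float) -> float:
    """Index of ideality of correlation.

    With residuals Δk = observed_k − calculated_k, MAE⁻ is the mean |Δ|
    over Δ < 0 and MAE⁺ the mean |Δ| over Δ >= 0; the IIC is the
    calibration correlation scaled by min(MAE⁻, MAE⁺)/max(MAE⁻, MAE⁺).
    If either residual class is empty the IIC is 0 by definition.
    """
    x, y = _pair(observed, calculated)
    delta = x - y
    neg = np.abs(delta[delta < 0])
    pos = np.abs(delta[delta >= 0])
    if neg.size == 0 or pos.size == 0:
        return 0.0
    mae_neg = float(neg.mean())
    mae_pos = float(pos.mean())
    hi = max(mae_neg, mae_pos)
    if hi == 0.0:
        return float(r_calibration)
    return float(r_calibration) * min(mae_neg, mae_pos) / hi


#: default Golbraikh–Tropsha acceptance thresholds
GT_DEFAULTS = {
    "r2_min": 0.6,
    "k_low": 0.85,
    "k_high": 1.15,
    "r0_gap_max": 0.1,
    "r0_diff_max": 0.3,
}


def golbraikh_tropsha(observed, predicted, thresholds: dict | None = None) -> dict:
    """Pass/fail flags of the Golbraikh–Tropsha external-validation checks."""
    t = dict(GT_DEFAULTS)
    if thresholds:
        t.update(thresholds)
    r2 = pearson_r(observed, predicted) ** 2
    k, k_prime, r0_sq, r0_sq_primed = through_origin(observed, predicted)
    return {
        "r2_ok": r2 > t["r2_min"],
        "k_ok": t["k_low"] <= k <= t["k_high"],
        "k_prime_ok": t["k_low"] <= k_prime <= t["k_high"],
        "r0_gap_ok": r2 > 0 and (r2 - r0_sq) / r2 < t["r0_gap_max"],
        "r0_diff_ok": abs(r0_sq - r0_sq_primed) < t["r0_diff_max"],
    }


@dataclass
class CriteriaReport:
    """All criteria for one (observed, predicted) pairing; None = undefined."""

    n: int
    r: Optional[float] = None
    r_squared: Optional[float] = None
    ccc: Optional[float] = None
    k: Optional[float] = None
    k_primed: Optional[float] = None
    r0_sq: Optional[float] = None
    r0_sq_primed: Optional[float] = None
    q2: Optional[float] = None
    q2_f1: Optional[float] = None
    q2_f2: Optional[float] = None
    q2_f3: Optional[float] = None
    rm2_avg: Optional[float] = None
    rm2_delta: Optional[float] = None
    iic: Optional[float] = None
    gt_flags: Optional[dict] = None

    def to_rows(self) -> list[tuple[str, Optional[float]]]:
        rows = [
            ("n", self.n), ("r", self.r), ("r_squared", self.r_squared),
            ("ccc", self.ccc), ("k", self.k), ("k_primed", self.k_primed),
            ("r0_sq", self.r0_sq), ("r0_sq_primed", self.r0_sq_primed),
            ("q2", self.q2), ("q2_f1", self.q2_f1), ("q2_f2", self.q2_f2),
            ("q2_f3", self.q2_f3), ("rm2_avg", self.rm2_avg),
            ("rm2_delta", self.rm2_delta), ("iic", self.iic),
        ]
        if self.gt_flags is not None:
            rows += [(f"gt_{k}", float(v)) for k, v in self.gt_flags.items()]
        return rows


def full_report(
    observed,
    predicted,
    ctx: Optional[TrainingContext] = None,
    r_calibration: Optional[float] = None,
    rm2_sqrt_form: bool = True,
    gt_thresholds: dict | None = None,
) -> CriteriaReport:
    """Assemble every criterion; undefined statistics are reported absent.

    ``r_calibration`` defaults to the correlation of this same pairing,
    the common choice when no separate calibration set exists.
    """
    x, y = _pair(observed, predicted)
    report = CriteriaReport(n=int(x.size))

    def attempt(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except UndefinedStatisticError:
            return None

    report.r = attempt(pearson_r, x, y)
    if report.r is not None:
        report.r_squared = report.r**2
    report.ccc = attempt(ccc, x, y)
    origin = attempt(through_origin, x, y)
    if origin is not None:
        report.k, report.k_primed, report.r0_sq, report.r0_sq_primed = origin
    q2s = attempt(q2_family, x, y, ctx)
    if q2s is not None:
        report.q2, report.q2_f1, report.q2_f2, report.q2_f3 = q2s
    rm2 = attempt(rm2_metrics, x, y, rm2_sqrt_form)
    if rm2 is not None:
        report.rm2_avg, report.rm2_delta = rm2
    r_cal = r_calibration if r_calibration is not None else report.r
    if r_cal is not None:
        report.iic = iic(x, y, r_cal)
    report.gt_flags = attempt(golbraikh_tropsha, x, y, gt_thresholds)
    return report
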