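"""Accuracy statistics for extracted-vs-measured trait comparisons.

Given paired sequences of manually measured values x_i and extracted values
x_hat_i, the module computes

    RMSE  = sqrt( sum (x_hat_i - x_i)^2 / n )
    RRMSE = 100 * RMSE / mean(x)            (percent, mean of the MEASURED)
    R^2   = coefficient of determination of the ordinary least-squares
            linear fit of extracted on measured (the squared Pearson
            correlation for a simple linear fit)

and bands RRMSE into difference categories: < 10% none, [10, 20)% small,
[20, 30)% moderate, >= 30% large.

A legacy R^2 variant, 1 - sum(x_hat_i - x_mean)^2 / sum(x_i - x_mean)^2, is
available behind ``formula="legacy"``; it is not the residual-based
statistic (it can exceed 1 and misses perfect non-identity fits) and exists
only for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .errors import EvaluationError

__all__ = [
    "PairedSample",
    "DifferenceCategory",
    "EvalReport",
    "rmse",
    "rrmse",
    "r_squared",
    "difference_category",
    "evaluate",
]


@dataclass(frozen=True)
class PairedSample:
    """Equal-length sequences of measured and extracted trait values."""

    measured: np.ndarray
    extracted: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.measured, dtype=np.float64).ravel()
        e = np.asarray(self.extracted, dtype=np.float64).ravel()
        if m.shape != e.shape:
            raise EvaluationError(
                f"measured ({m.size}) and extracted ({e.size}) differ in length"
            )
        if m.size < 1:
            raise EvaluationError("paired sample is empty")
        if not (np.isfinite(m).all() and np.isfinite(e).all()):
            raise EvaluationError("paired sample contains non-finite values")
        object.__setattr__(self, "measured", m)
        object.__setattr__(self, "extracted", e)

    @property
    def n(self) -> int:
        return self.measured.size


class DifferenceCategory(str, Enum):
    NONE = "none"
    SMALL = "small"
    MODERATE = "moderate"
    LARGE = "large"


@dataclass(frozen=True)
class EvalReport:
    r2: float
    rmse: float
    rrmse: float            # percent
    category: DifferenceCategory
    n: int


def rmse(sample: PairedSample) -> float:
    d = sample.extracted - sample.measured
    return float(np.sqrt(np.mean(d * d)))


def rrmse(sample: PairedSample) -> float:
    """RMSE relative to the mean of the measured values, in percent."""
    x_bar = float(sample.measured.mean())
    if x_bar == 0.0:
        raise EvaluationError("RRMSE undefined: mean of measured values is zero")
    return 100.0 * rmse(sample) / x_bar


def r_squared(sample: PairedSample, formula: str = "fit") -> float:
    """Coefficient of determination of the linear fit of extracted on
    measured (``formula="fit"``), or the legacy anomaly-ratio variant
    (``formula="legacy"``)."""
    if sample.n < 2:
        raise EvaluationError("R^2 needs at least 2 pairs")
    m, e = sample.measured, sample.extracted
    if np.ptp(m) == 0.0:
        raise EvaluationError("R^2 undefined for constant measured values")
    if formula == "fit":
        if np.ptp(e) == 0.0:
            return 0.0
        r = stats.pearsonr(m, e).statistic
        return float(r * r)
    if formula == "legacy":
        x_bar = m.mean()
        return float(1.0 - np.sum((e - x_bar) ** 2) / np.sum((m - x_bar) ** 2))
    raise ValueError(f"unknown R^2 formula '{formula}' (fit/legacy)")


def difference_category(rrmse_pct: float) -> DifferenceCategory:
    """Band an RRMSE percentage; boundaries are left-closed at 10, 20, 30."""
    if rrmse_pct < 10.0:
        return DifferenceCategory.NONE
    if rrmse_pct < 20.0:
        return DifferenceCategory.SMALL
    if rrmse_pct < 30.0:
        return DifferenceCategory.MODERATE
    return DifferenceCategory.LARGE


def evaluate(sample: PairedSample, formula: str = "fit") -> EvalReport:
    """All four statistics for one trait."""
    err = rrmse(sample)
    return EvalReport(
        r2=r_squared(sample, formula=formula),
        rmse=rmse(sample),
        rrmse=err,
        category=difference_category(err),
        n=sample.n,
    )
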