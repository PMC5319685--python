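"""Forecast evaluation criteria and seasonal-fluctuation analysis.

Level criteria: Pearson correlation R between forecast and observation,
root mean squared error (RMSE), mean absolute percentage error (MAPE,
returned as a fraction), and the sum of squared errors (SSE = n * RMSE^2).

Seasonality: SFI1 measures how far each calendar month's multi-year mean
sits from the overall mean (|mean_month - mean_all| / mean_all); SFI2 does
the same per step of a test segment against the segment mean; the per-step
relative error |forecast - observed| / observed relates forecast accuracy
to seasonal swing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidInputError
from .series import TimeSeries

__all__ = [
    "MetricBundle",
    "SeasonalIndices",
    "r_criterion",
    "rmse",
    "mape",
    "sse",
    "evaluate",
    "sfi1",
    "sfi2",
    "relative_error",
]


@dataclass(frozen=True)
class MetricBundle:
    """The four level-prediction criteria for one forecast horizon."""

    R: float
    RMSE: float
    MAPE: float  # fraction, not percent
    SSE: float
    n: int


@dataclass(frozen=True)
class SeasonalIndices:
    """Seasonal fluctuation of a series and per-step forecast error."""

    sfi1_by_month: np.ndarray  # 12 values, index 0 = January
    sfi2_by_step: np.ndarray
    relative_errors: np.ndarray


def _paired(predicted, observed) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.size != o.size:
        raise InvalidInputError(f"length mismatch: {p.size} vs {o.size}")
    return p, o


def r_criterion(predicted, observed) -> float:
    """Pearson linear correlation coefficient, in [-1, 1]."""
    p, o = _paired(predicted, observed)
    if p.size < 2:
        raise InvalidInputError("correlation needs >= 2 points")
    if np.ptp(p) == 0 or np.ptp(o) == 0:
        raise DegenerateInputError("correlation undefined for a constant input")
    pc = p - p.mean()
    oc = o - o.mean()
    return float(np.dot(pc, oc) / np.sqrt(np.dot(pc, pc) * np.dot(oc, oc)))


def rmse(predicted, observed) -> float:
    p, o = _paired(predicted, observed)
    if p.size < 1:
        raise InvalidInputError("RMSE needs >= 1 point")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def mape(predicted, observed) -> float:
    """Mean of |forecast - observed| / |observed|, as a fraction."""
    p, o = _paired(predicted, observed)
    if np.any(o == 0):
        raise DegenerateInputError("MAPE undefined when an observed value is zero")
    return float(np.mean(np.abs(p - o) / np.abs(o)))


def sse(predicted, observed) -> float:
    p, o = _paired(predicted, observed)
    return float(np.sum((p - o) ** 2))


def evaluate(predicted, observed) -> MetricBundle:
    """All four criteria in one bundle."""
    p, o = _paired(predicted, observed)
    return MetricBundle(
        R=r_criterion(p, o),
        RMSE=rmse(p, o),
        MAPE=mape(p, o),
        SSE=sse(p, o),
        n=p.size,
    )


def sfi1(series: TimeSeries) -> np.ndarray:
    """Seasonal fluctuation index per calendar month.

    Uses the full calendar years the series contains, averaging each
    month's observations across years.  Index 0 is January.
    """
    values = series.values
    months = np.array([m for (_, m) in series.labels])
    counts = np.array([np.sum(months == c) for c in range(1, 13)])
    if np.min(counts) < 2:
        raise InvalidInputError("SFI1 needs >= 2 observations of every calendar month")
    overall = float(values.mean())
    if overall == 0:
        raise DegenerateInputError("SFI1 undefined for a zero-mean series")
    out = np.empty(12)
    for c in range(1, 13):
        out[c - 1] = abs(values[months == c].mean() - overall) / abs(overall)
    return out


def sfi2(test_segment) -> np.ndarray:
    """Per-step fluctuation of a segment around its own mean."""
    x = np.asarray(test_segment, dtype=float).ravel()
    mean = float(x.mean())
    if mean == 0:
        raise DegenerateInputError("SFI2 undefined for a zero-mean segment")
    return np.abs(x - mean) / abs(mean)


def relative_error(predicted, observed) -> np.ndarray:
    """Per-step |forecast - observed| / observed."""
    p, o = _paired(predicted, observed)
    if np.any(o == 0):
        raise DegenerateInputError("relative error undefined for zero observations")
    return np.abs(p - o) / o


def seasonal_report(series: TimeSeries, predicted, observed) -> SeasonalIndices:
    """Bundle SFI1 of the full series with SFI2 and RE of the test horizon."""
    return SeasonalIndices(
        sfi1_by_month=sfi1(series),
        sfi2_by_step=sfi2(observed),
        relative_errors=relative_error(predicted, observed),
    )
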