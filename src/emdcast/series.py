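"""Monthly time-series container.

A :class:`TimeSeries` is an ordered sequence of real observations, one per
calendar month, with contiguous ``(year, month)`` labels.  The internal
index is the 0-based month offset from the series start; labels carry the
calendar information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

Month = tuple[int, int]  # (year, month), month in 1..12


def month_index(start: Month, m: Month) -> int:
    """0-based offset of calendar month ``m`` from ``start``."""
    return (m[0] - start[0]) * 12 + (m[1] - start[1])


def add_months(start: Month, k: int) -> Month:
    """Calendar month ``k`` steps after ``start`` (k may be negative)."""
    total = start[0] * 12 + (start[1] - 1) + k
    return total // 12, total % 12 + 1


def format_month(m: Month) -> str:
    return f"{m[0]:04d}-{m[1]:02d}"


def parse_month(text: str) -> Month:
    """Parse ``YYYY-MM`` into a (year, month) pair."""
    parts = text.strip().split("-")
    if len(parts) != 2:
        raise InvalidInputError(f"expected YYYY-MM, got {text!r}")
    try:
        year, month = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise InvalidInputError(f"expected YYYY-MM, got {text!r}") from exc
    if not 1 <= month <= 12:
        raise InvalidInputError(f"month out of range in {text!r}")
    return year, month


@dataclass(frozen=True)
class TimeSeries:
    """Ordered monthly observations x(t) with calendar labels.

    Parameters
    ----------
    values
        Finite real observations, length >= 2.
    start
        Calendar (year, month) of the first observation.  Labels are
        implied: observation t belongs to ``start`` advanced by t months.
    """

    values: np.ndarray
    start: Month
    labels: tuple[Month, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise InvalidInputError("a monthly series needs >= 1 observation")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("series values must be finite")
        if not 1 <= self.start[1] <= 12:
            raise InvalidInputError(f"start month out of range: {self.start}")
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "labels", tuple(add_months(self.start, k) for k in range(values.size))
        )

    def __len__(self) -> int:
        return self.values.size

    @property
    def end(self) -> Month:
        return self.labels[-1]

    def slice(self, i: int, j: int) -> "TimeSeries":
        """Sub-series covering index range [i, j) with shifted start label."""
        if not (0 <= i < j <= len(self)):
            raise InvalidInputError(f"bad slice [{i}, {j}) of length-{len(self)} series")
        return TimeSeries(self.values[i:j].copy(), add_months(self.start, i))

    def index_of(self, m: Month) -> int:
        k = month_index(self.start, m)
        if not 0 <= k < len(self):
            raise InvalidInputError(
                f"month {format_month(m)} outside series span "
                f"{format_month(self.start)}..{format_month(self.end)}"
            )
        return k
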