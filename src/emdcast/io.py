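"""Readers and writers for monthly series and forecast reports.

All readers validate rather than repair: a missing calendar month, an
unparseable value or a wrong span raises an error naming its location.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .emd import Decomposition, SiftConfig
from .errors import GapError, InvalidInputError, ParseError
from .forecaster import ForecastReport
from .mlp import TrainConfig
from .pso import PSOConfig
from .series import Month, TimeSeries, add_months, format_month, parse_month
from .synthetic import SimConfig

__all__ = [
    "read_monthly_csv",
    "write_monthly_csv",
    "read_s1_xls",
    "write_decomposition",
    "write_report",
    "load_run_config",
]


def read_monthly_csv(path: str | Path) -> TimeSeries:
    """Read a two-column ``date,value`` CSV with ``YYYY-MM`` dates into a
    contiguous monthly series."""
    path = Path(path)
    months: list[Month] = []
    values: list[float] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["date", "value"]:
            raise ParseError(f"{path}: expected header 'date,value', got {header}")
        for row_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}: row {row_no}: expected 2 columns")
            try:
                month = parse_month(row[0])
            except InvalidInputError as exc:
                raise ParseError(f"{path}: row {row_no}: {exc}") from exc
            try:
                value = float(row[1])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: row {row_no}: unparseable value {row[1]!r}"
                ) from exc
            months.append(month)
            values.append(value)
    if len(months) < 2:
        raise ParseError(f"{path}: need at least 2 data rows")
    for k in range(1, len(months)):
        expected = add_months(months[0], k)
        if months[k] != expected:
            raise GapError(
                f"{path}: missing month {format_month(expected)} "
                f"(found {format_month(months[k])} after {format_month(months[k - 1])})"
            )
    return TimeSeries(np.asarray(values), months[0])


def write_monthly_csv(series: TimeSeries, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["date", "value"])
        for label, value in zip(series.labels, series.values):
            writer.writerow([format_month(label), repr(float(value))])


def read_s1_xls(path: str | Path, start: Month = (2005, 1)) -> TimeSeries:
    """Read a single-sheet workbook of monthly outpatient counts.

    Accepts either a 108-cell list layout (one value per row, in month
    order, with or without a date column) or a years x 12 grid; the
    detected layout is reported in the error message if validation fails.
    Expects exactly 9 years (108 months) starting January 2005.
    """
    path = Path(path)
    frame = pd.read_excel(path, header=None)
    frame = frame.dropna(how="all").dropna(axis=1, how="all")
    if frame.empty:
        raise ParseError(f"{path}: empty sheet")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.shape[1] >= 12 and numeric.iloc[:, -12:].notna().all().all():
        # grid layout: one row per year, last 12 numeric columns = months
        values = numeric.iloc[:, -12:].to_numpy(dtype=float).ravel()
        layout = f"{numeric.shape[0]}x12 grid"
    else:
        col = numeric.iloc[:, -1]
        bad = col.index[col.isna() & frame.iloc[:, -1].notna()]
        if len(bad):
            cell = frame.iloc[bad[0], -1]
            raise ParseError(f"{path}: non-numeric cell {cell!r} at row {bad[0] + 1}")
        values = col.dropna().to_numpy(dtype=float)
        layout = "single-column list"
    if values.size != 108:
        raise InvalidInputError(
            f"{path}: expected 108 monthly values (Jan 2005-Dec 2013), "
            f"found {values.size} ({layout})"
        )
    return TimeSeries(values, start)


def write_decomposition(
    decomposition: Decomposition, series: TimeSeries, path: str | Path
) -> None:
    """Write ``date,imf1..imfm,residue`` rows aligned with the series."""
    if decomposition.source_length != len(series):
        raise InvalidInputError("decomposition length does not match series")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["date"]
            + [f"imf{i + 1}" for i in range(decomposition.n_imfs)]
            + ["residue"]
        )
        for t, label in enumerate(series.labels):
            row = [format_month(label)]
            row += [repr(float(g[t])) for g in decomposition.imfs]
            row.append(repr(float(decomposition.residue[t])))
            writer.writerow(row)


def write_report(report: ForecastReport, out_dir: str | Path) -> dict[str, Path]:
    """Write predictions, per-component predictions, and the metrics row.

    Values are written with full precision so a read-back reproduces them
    exactly.  Returns the paths written, keyed by artifact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_comp = report.per_component_predicted.shape[1]

    pred_path = out_dir / "predictions.csv"
    with pred_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["date", "observed", "predicted"]
            + [f"component_{k + 1}" for k in range(n_comp)]
        )
        for s, label in enumerate(report.horizon_labels):
            row = [
                format_month(label),
                repr(float(report.observed[s])),
                repr(float(report.predicted[s])),
            ]
            row += [repr(float(v)) for v in report.per_component_predicted[s]]
            writer.writerow(row)

    metrics_path = out_dir / "metrics.csv"
    with metrics_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["R", "RMSE", "MAPE", "SSE", "n"])
        m = report.metrics
        writer.writerow([repr(m.R), repr(m.RMSE), repr(m.MAPE), repr(m.SSE), m.n])

    return {"predictions": pred_path, "metrics": metrics_path}


_SECTION_TYPES = {
    "sift": SiftConfig,
    "train": TrainConfig,
    "pso": PSOConfig,
    "sim": SimConfig,
}
_TOP_KEYS = set(_SECTION_TYPES) | {"seed"}


def load_run_config(path: str | Path) -> dict:
    """Parse a YAML run configuration with sections sift/train/pso/sim and
    an optional top-level master ``seed``.  Unknown keys are rejected."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ParseError(f"{path}: unknown top-level keys {sorted(unknown)}")
    out: dict = {"seed": int(raw.get("seed", 0))}
    for section, cls in _SECTION_TYPES.items():
        kwargs = raw.get(section, {}) or {}
        if not isinstance(kwargs, dict):
            raise ParseError(f"{path}: section {section!r} must be a mapping")
        valid = set(cls.__dataclass_fields__)
        bad = set(kwargs) - valid
        if bad:
            raise ParseError(f"{path}: unknown keys {sorted(bad)} in section {section!r}")
        try:
            out[section] = cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: section {section!r}: {exc}") from exc
    return out
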