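"""Monthly monitoring time series with seasonal gaps.

Lake monitoring campaigns sample plankton and water temperature once a month
during the ice-free season, so a multi-year record is a sequence of short
runs of consecutive months separated by unsampled winters.  This module
defines the containers for such records, CSV input/output (header
``year,month,value``, missing cells empty or ``NA``), timestamp alignment,
and the decomposition of a record into season runs — the maximal blocks of
consecutive calendar months on which all difference-based computations
downstream are allowed to operate.

Sample positions are 0-based; calendar identity lives only in the
(year, month) pair attached to each sample.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from typing import NamedTuple, Sequence

import numpy as np

from .errors import AlignmentError, FormatError, ValidationError

VARIABLES = ("phytoplankton", "zooplankton", "temperature")
ABUNDANCE_VARIABLES = ("phytoplankton", "zooplankton")

#: sentinel written for missing values; parsed case-insensitively
NA_SENTINEL = "NA"


class TimeStamp(NamedTuple):
    """A calendar month: (year, month) with month in 1..12."""

    year: int
    month: int

    @property
    def month_index(self) -> int:
        """Months since year 0; consecutive months differ by exactly 1."""
        return self.year * 12 + (self.month - 1)


@dataclasses.dataclass
class MonitoringSeries:
    """One monitored variable in one lake on a monthly, gappy timeline.

    ``values`` uses NaN for missing observations.  Abundance variables
    (phytoplankton, zooplankton) must be strictly positive where observed
    because they appear in denominators of the model inversion; temperature
    may be any real number.
    """

    lake: str
    variable: str
    years: np.ndarray
    months: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.months = np.asarray(self.months, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if not (self.years.shape == self.months.shape == self.values.shape):
            raise ValidationError("years, months and values must have equal length")
        if self.years.ndim != 1:
            raise ValidationError("series arrays must be one-dimensional")
        if self.variable not in VARIABLES:
            raise ValidationError(
                f"unknown variable {self.variable!r}; expected one of {VARIABLES}"
            )
        if np.any((self.months < 1) | (self.months > 12)):
            raise ValidationError("months must lie in 1..12")
        mi = self.month_index
        if np.any(np.diff(mi) <= 0):
            raise ValidationError("timestamps must be unique and strictly increasing")
        if self.variable in ABUNDANCE_VARIABLES:
            observed = self.values[~np.isnan(self.values)]
            if np.any(observed <= 0):
                raise ValidationError(
                    f"{self.variable} abundances must be > 0 where observed"
                )

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n

    @property
    def month_index(self) -> np.ndarray:
        """Linear month coordinate (year*12 + month-1); gap-aware."""
        return self.years * 12 + (self.months - 1)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def timestamps(self) -> list[TimeStamp]:
        return [TimeStamp(int(y), int(m)) for y, m in zip(self.years, self.months)]

    def equals(self, other: "MonitoringSeries") -> bool:
        return (
            self.lake == other.lake
            and self.variable == other.variable
            and self.units == other.units
            and np.array_equal(self.years, other.years)
            and np.array_equal(self.months, other.months)
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclasses.dataclass(frozen=True)
class SeasonRun:
    """A maximal run of consecutive calendar months, as 0-based sample positions."""

    start_index: int
    end_index: int  # inclusive

    @property
    def length(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start_index, self.end_index + 1)


def season_runs(series: MonitoringSeries) -> list[SeasonRun]:
    """Partition sample positions into maximal runs of consecutive months.

    Every index belongs to exactly one run; runs are separated by calendar
    gaps of at least one month (typically the unsampled winter).
    """
    if series.n == 0:
        raise ValidationError("cannot compute season runs of an empty series")
    mi = series.month_index
    breaks = np.flatnonzero(np.diff(mi) != 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [series.n - 1]))
    return [SeasonRun(int(s), int(e)) for s, e in zip(starts, ends)]


def run_ids(series: MonitoringSeries) -> np.ndarray:
    """Per-sample season-run label (0-based, in chronological order)."""
    ids = np.empty(series.n, dtype=np.int64)
    for k, run in enumerate(season_runs(series)):
        ids[run.start_index : run.end_index + 1] = k
    return ids


def align_series(
    a: MonitoringSeries, b: MonitoringSeries
) -> tuple[MonitoringSeries, MonitoringSeries]:
    """Restrict both series to their common timestamps, preserving order."""
    if a.n == 0 or b.n == 0:
        raise AlignmentError("cannot align an empty series")
    _, ia, ib = np.intersect1d(a.month_index, b.month_index, return_indices=True)
    if ia.size == 0:
        raise AlignmentError(
            f"series share no timestamps ({a.lake}/{a.variable} vs {b.lake}/{b.variable})"
        )
    ia.sort()
    ib.sort()
    return _take(a, ia), _take(b, ib)


def _take(series: MonitoringSeries, idx: np.ndarray) -> MonitoringSeries:
    return dataclasses.replace(
        series,
        years=series.years[idx],
        months=series.months[idx],
        values=series.values[idx],
    )


def read_series(path, lake: str, variable: str) -> MonitoringSeries:
    """Read one ``year,month,value`` CSV into a validated MonitoringSeries.

    Empty cells or the literal ``NA`` (case-insensitive) mark missing values.
    Rows are sorted into calendar order; duplicate timestamps are an error.
    """
    rows: list[tuple[int, int, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        header = [h.strip().lower() for h in header]
        if header[:3] != ["year", "month", "value"]:
            raise FormatError(
                f"{path}: expected header 'year,month,value', got {','.join(header)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            try:
                year = int(row[0])
                month = int(row[1])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: unparseable year/month {row[0]!r},{row[1]!r}"
                ) from None
            cell = row[2].strip()
            if cell == "" or cell.upper() == NA_SENTINEL:
                value = math.nan
            else:
                try:
                    value = float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: unparseable value {cell!r}"
                    ) from None
            rows.append((year, month, value))
    if not rows:
        raise FormatError(f"{path}: no data rows")
    rows.sort(key=lambda r: (r[0], r[1]))
    keys = [(y, m) for y, m, _ in rows]
    for k in range(1, len(keys)):
        if keys[k] == keys[k - 1]:
            raise FormatError(f"{path}: duplicate timestamp {keys[k]}")
    years, months, values = (np.asarray(col) for col in zip(*rows))
    return MonitoringSeries(lake=lake, variable=variable, years=years, months=months, values=values)


def write_series(series, path) -> None:
    """Write a monitoring or derived series as CSV; round-trips losslessly.

    Missing values become ``NA``.  Derived series (anything carrying a
    ``run_ids`` attribute) get a fourth ``run_id`` column.
    """
    derived = hasattr(series, "run_ids")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if derived:
            writer.writerow(["year", "month", "value", "run_id"])
            for y, m, v, r in zip(series.years, series.months, series.values, series.run_ids):
                writer.writerow([int(y), int(m), _fmt(v), int(r)])
        else:
            writer.writerow(["year", "month", "value"])
            for y, m, v in zip(series.years, series.months, series.values):
                writer.writerow([int(y), int(m), _fmt(v)])


def _fmt(value: float) -> str:
    # repr() gives the shortest digit string that round-trips the float
    return NA_SENTINEL if math.isnan(value) else repr(float(value))
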