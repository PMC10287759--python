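"""Seasonal-split missing-value imputation for monthly monitoring series.

Monitoring series with an annual cycle should not be interpolated across the
raw timeline: a missing June would then be filled from a May and a July of
the same year and inherit the seasonal slope rather than the typical June
level.  Instead the series is split by calendar month — all Junes form one
sub-series ordered by year — and each missing value is filled by linear
interpolation across years *within its own month slice*.  A missing value
before the first (after the last) observation of its slice is filled with
that nearest observed value, so imputed values never leave the observed
range of their slice.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ImputationError
from .timeseries_io import MonitoringSeries


def impute_seasonal(series: MonitoringSeries) -> MonitoringSeries:
    """Fill every missing value by month-slice linear interpolation.

    Observed values are never modified; the operation is idempotent.
    Raises :class:`ImputationError` if some calendar month has a missing
    value but no observation at all to interpolate from.
    """
    missing = series.missing
    if not missing.any():
        return dataclasses.replace(series)
    values = series.values.copy()
    for month in np.unique(series.months[missing]):
        in_slice = series.months == month
        observed = in_slice & ~missing
        if not observed.any():
            raise ImputationError(
                f"calendar month {int(month)} has no observed values; "
                "cannot impute its missing entries"
            )
        fill = in_slice & missing
        # years within one month slice are strictly increasing (calendar order)
        values[fill] = np.interp(
            series.years[fill], series.years[observed], series.values[observed]
        )
    return dataclasses.replace(series, values=values)
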