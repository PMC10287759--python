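"""Algebraic inversion of a discrete prey–predator model.

The phytoplankton (prey, P) / zooplankton (predator, Z) dynamics are modelled
on a monthly grid as

    ΔP(n)/P(n) = G(n) − f(n)·Z(n)
    ΔZ(n)/Z(n) = β·f(n)·P(n) − α

with ΔX(n) = X(n+1) − X(n).  Instead of prescribing the intrinsic growth
rate G and the predation intensity f analytically and solving forward, the
monitoring series P(n), Z(n) are inserted directly into the equations and the
unknown functional terms are solved for as time series:

    G(n) = (β·ΔP(n) + ΔZ(n) + α·Z(n)) / (β·P(n))
    f(n) = (ΔZ(n)/Z(n) + α) / (β·P(n))

α (month⁻¹) is the intensity of predator decline unrelated to grazing; β is
the efficiency of converting consumed prey into predator abundance, ≈ 0.1 by
Lindeman's 10% rule.  G(n) may legitimately be negative.

Forward differences need a same-season successor, so the last sample of each
season run carries no derived value and the step across a winter gap is
omitted, never bridged.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import AlignmentError, DomainError, ValidationError
from .timeseries_io import MonitoringSeries, run_ids, season_runs

#: default admissible range for alpha, month^-1
DEFAULT_ALPHA_BOUNDS = (0.0, 20.0)


@dataclasses.dataclass(frozen=True)
class KDDParams:
    """Model constants: alpha (month⁻¹) ≥ 0 and beta > 0 (conversion efficiency).

    ``alpha_bounds`` is a validation range, not a fitting constraint; the
    default span covers the values consistent with lake monitoring.
    """

    alpha: float = 1.0
    beta: float = 0.1
    alpha_bounds: tuple[float, float] = DEFAULT_ALPHA_BOUNDS

    def __post_init__(self) -> None:
        lo, hi = self.alpha_bounds
        if not lo <= self.alpha <= hi:
            raise ValidationError(
                f"alpha={self.alpha} outside admissible range [{lo}, {hi}]"
            )
        if not self.beta > 0:
            raise ValidationError(f"beta must be > 0, got {self.beta}")


@dataclasses.dataclass
class DerivedSeries:
    """A model-derived series (G or f) on the valid within-season index set.

    ``run_ids`` labels the season run each sample came from; the last sample
    of every run in the source data is absent here by construction.
    """

    variable: str  # "G" or "f"
    years: np.ndarray
    months: np.ndarray
    values: np.ndarray
    run_ids: np.ndarray
    params: KDDParams

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.months = np.asarray(self.months, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        self.run_ids = np.asarray(self.run_ids, dtype=np.int64)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def month_index(self) -> np.ndarray:
        return self.years * 12 + (self.months - 1)


def _check_inputs(P: MonitoringSeries, Z: MonitoringSeries) -> None:
    if not np.array_equal(P.month_index, Z.month_index):
        raise AlignmentError("P and Z must be on identical timestamps; align first")
    if P.missing.any() or Z.missing.any():
        raise ValidationError("P and Z must be fully observed; impute first")


def valid_steps(series: MonitoringSeries) -> np.ndarray:
    """Indices n whose successor n+1 lies in the same season run."""
    runs = season_runs(series)
    return np.concatenate(
        [np.arange(r.start_index, r.end_index) for r in runs if r.length > 1]
        or [np.empty(0, dtype=np.int64)]
    ).astype(np.int64)


def growth_rate(
    P: MonitoringSeries, Z: MonitoringSeries, params: KDDParams
) -> DerivedSeries:
    """Recover the intrinsic prey growth-rate series G(n).

    G(n) = (β·(P(n+1)−P(n)) + (Z(n+1)−Z(n)) + α·Z(n)) / (β·P(n)) at every
    index n with a same-season successor; cross-season steps are omitted.
    """
    _check_inputs(P, Z)
    if np.any(P.values <= 0):
        raise DomainError("P(n) must be > 0 everywhere (appears in the denominator)")
    n_idx = valid_steps(P)
    dP = P.values[n_idx + 1] - P.values[n_idx]
    dZ = Z.values[n_idx + 1] - Z.values[n_idx]
    g = (params.beta * dP + dZ + params.alpha * Z.values[n_idx]) / (
        params.beta * P.values[n_idx]
    )
    return DerivedSeries(
        variable="G",
        years=P.years[n_idx],
        months=P.months[n_idx],
        values=g,
        run_ids=run_ids(P)[n_idx],
        params=params,
    )


def trophic_function(
    P: MonitoringSeries, Z: MonitoringSeries, params: KDDParams
) -> DerivedSeries:
    """Recover the predation-intensity series f(n) = (ΔZ(n)/Z(n) + α) / (β·P(n))."""
    _check_inputs(P, Z)
    if np.any(P.values <= 0):
        raise DomainError("P(n) must be > 0 everywhere")
    if np.any(Z.values <= 0):
        raise DomainError("Z(n) must be > 0 everywhere (appears in the denominator)")
    n_idx = valid_steps(P)
    dZ = Z.values[n_idx + 1] - Z.values[n_idx]
    f = (dZ / Z.values[n_idx] + params.alpha) / (params.beta * P.values[n_idx])
    return DerivedSeries(
        variable="f",
        years=P.years[n_idx],
        months=P.months[n_idx],
        values=f,
        run_ids=run_ids(P)[n_idx],
        params=params,
    )
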