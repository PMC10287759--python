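"""Generator of monitoring-like lake data with known ground truth.

Emulates what a long-term lake monitoring programme records: multi-year
series sampled monthly during a warm season of consecutive months, a
near-periodic seasonal water temperature, plankton abundances produced by
the same discrete prey–predator model the inversion assumes, additive
observation noise, and randomly missing values.  Because the prescribed
growth-rate signal G* and trophic intensity f* are known, the generator
doubles as the central oracle for the inversion: applying
:func:`planksync.kdd_inversion.growth_rate` to a simulated (P, Z) pair must
return G* exactly (to floating point), since the inversion formula is the
algebraic rearrangement of the forward update.

Temperature coupling is injected through the seasonal *phase*: G* is driven
by the same seasonal angle that generates temperature, shifted by
``growth_phase_lag``.  Setting ``growth_amplitude = 0`` (noise-only growth)
gives the matched uncoupled condition for power/false-positive studies.
Prey and predator are re-initialized at each season start, standing in for
unmodelled overwintering; the model is only ever applied within seasons.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .errors import SimulationError, ValidationError
from .kdd_inversion import DerivedSeries, KDDParams
from .timeseries_io import MonitoringSeries, run_ids, season_runs

# fixed sub-stream labels so each randomness source is independent of the others
_STREAM_TEMP = 1
_STREAM_GROWTH = 2
_STREAM_MISSING_P = 3
_STREAM_MISSING_Z = 4
_STREAM_MISSING_T = 5
_STREAM_OBSNOISE_P = 6
_STREAM_OBSNOISE_Z = 7


@dataclasses.dataclass(frozen=True)
class SimSpec:
    """Study conditions for one synthetic monitoring campaign.

    Defaults describe a two-decade temperate-lake programme sampling a
    six-month open-water season (May–October): mean summer water temperature
    13 °C swinging ±7 °C over the season, phytoplankton around a few mg/l,
    zooplankton decline α = 0.5 month⁻¹ and Lindeman conversion β = 0.1,
    growth rate oscillating 0.5 ± 0.3 month⁻¹ in phase with temperature.
    """

    n_years: int = 20
    months_per_season: int = 6
    start_year: int = 2001
    season_start_month: int = 5
    temp_mean: float = 13.0
    temp_amplitude: float = 7.0
    temp_noise_sd: float = 1.0
    temp_phase: float = -np.pi / 2  # puts the temperature peak mid-season
    growth_mean: float = 0.5
    growth_amplitude: float = 0.3
    growth_phase_lag: float = 0.0
    growth_noise_sd: float = 0.05
    f_const: float = 1.0
    params: KDDParams = dataclasses.field(default_factory=lambda: KDDParams(alpha=0.5, beta=0.1))
    P0: float = 5.0
    Z0: float = 0.3
    missing_fraction: float = 0.03
    #: multiplicative log-normal observation noise on the reported P, Z
    #: (median-1 factors exp(N(0, cv)); 0 disables).  The noise degrades the
    #: periodicity of the *observed* abundances without touching the model
    #: trajectory, which stays the inversion ground truth.
    obs_noise_cv: float = 0.0
    seed: int = 0
    lake: str = "synthetic"

    def __post_init__(self) -> None:
        if not 3 <= self.months_per_season <= 12:
            raise ValidationError("months_per_season must lie in [3, 12]")
        if self.n_years < 1:
            raise ValidationError("n_years must be >= 1")
        if not (1 <= self.season_start_month <= 12):
            raise ValidationError("season_start_month must lie in 1..12")
        if self.P0 <= 0 or self.Z0 <= 0:
            raise ValidationError("initial abundances P0, Z0 must be > 0")
        if not 0.0 <= self.missing_fraction <= 0.2:
            raise ValidationError("missing_fraction must lie in [0, 0.2]")
        if self.obs_noise_cv < 0:
            raise ValidationError("obs_noise_cv must be >= 0")


@dataclasses.dataclass
class SimResult:
    """Everything one simulated campaign produced, ground truth included."""

    spec: SimSpec
    temperature: MonitoringSeries
    phytoplankton: MonitoringSeries
    zooplankton: MonitoringSeries
    phytoplankton_full: MonitoringSeries
    zooplankton_full: MonitoringSeries
    temperature_full: MonitoringSeries
    g_true: DerivedSeries
    f_true: DerivedSeries


def _calendar(spec: SimSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(years, months, month_in_season) for every in-season sample."""
    month_in_season = np.tile(np.arange(spec.months_per_season), spec.n_years)
    year_no = np.repeat(np.arange(spec.n_years), spec.months_per_season)
    month0 = spec.season_start_month - 1 + month_in_season
    years = spec.start_year + year_no + month0 // 12
    months = month0 % 12 + 1
    return years, months, month_in_season


def seasonal_angle(spec: SimSpec) -> np.ndarray:
    """The seasonal phase angle driving temperature (and coupled growth)."""
    _, _, m = _calendar(spec)
    return 2.0 * np.pi * m / spec.months_per_season + spec.temp_phase


def generate_temperature(spec: SimSpec) -> MonitoringSeries:
    """Near-periodic seasonal water temperature, in-season months only."""
    years, months, _ = _calendar(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _STREAM_TEMP]))
    values = spec.temp_mean + spec.temp_amplitude * np.sin(seasonal_angle(spec))
    if spec.temp_noise_sd > 0:
        values = values + rng.normal(0.0, spec.temp_noise_sd, size=years.size)
    return MonitoringSeries(
        lake=spec.lake, variable="temperature", years=years, months=months,
        values=np.asarray(values, dtype=np.float64), units="degC",
    )


def prescribed_growth(spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    """G*(n): seasonal-phase-driven sinusoid plus Gaussian noise, all samples."""
    g = spec.growth_mean + spec.growth_amplitude * np.sin(
        seasonal_angle(spec) + spec.growth_phase_lag
    )
    if spec.growth_noise_sd > 0:
        g = g + rng.normal(0.0, spec.growth_noise_sd, size=g.size)
    return g


def forward_simulate(
    spec: SimSpec, max_rejections: int = 20
) -> tuple[MonitoringSeries, MonitoringSeries, DerivedSeries, DerivedSeries]:
    """Run the prey–predator model forward under a prescribed G*, f*.

    Within each season run: P(n+1) = P(n)·(1 + G*(n) − f*·Z(n)) and
    Z(n+1) = Z(n)·(1 + β·f*·P(n) − α); at each season start P, Z restart
    from (P0, Z0).  A trajectory that would drive P or Z to ≤ 0 is rejected
    with a warning naming the offending step and re-drawn with fresh growth
    noise; a noiseless non-viable spec raises :class:`SimulationError`.

    Returns (P, Z, G_true, f_true) with the truths on the valid index set
    (every sample with a same-season successor).
    """
    years, months, m_in_season = _calendar(spec)
    n = years.size
    # a sample starts a new run iff the previous calendar month was unsampled;
    # a 12-month season has no winter gap, hence a single continuous run
    month_index = years * 12 + (months - 1)
    new_run = np.ones(n, dtype=bool)
    new_run[1:] = np.diff(month_index) != 1
    growth_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _STREAM_GROWTH]))
    alpha, beta = spec.params.alpha, spec.params.beta
    for attempt in range(max_rejections + 1):
        g_star = prescribed_growth(spec, growth_rng)
        P = np.empty(n)
        Z = np.empty(n)
        bad_step = None
        for i in range(n):
            if new_run[i]:
                P[i], Z[i] = spec.P0, spec.Z0
            else:
                P[i] = P[i - 1] * (1.0 + g_star[i - 1] - spec.f_const * Z[i - 1])
                Z[i] = Z[i - 1] * (1.0 + beta * spec.f_const * P[i - 1] - alpha)
                if P[i] <= 0 or Z[i] <= 0:
                    bad_step = i
                    break
        if bad_step is None:
            break
        msg = (
            f"trajectory rejected: non-positive abundance at step {bad_step} "
            f"(year {years[bad_step]}, month {months[bad_step]})"
        )
        if spec.growth_noise_sd == 0:
            raise SimulationError(msg + "; spec is deterministically non-viable")
        warnings.warn(msg + "; re-drawing growth noise", stacklevel=2)
    else:
        raise SimulationError(
            f"no viable trajectory in {max_rejections} redraws; spec too extreme"
        )
    P_series = MonitoringSeries(
        lake=spec.lake, variable="phytoplankton", years=years, months=months,
        values=P, units="mg/l",
    )
    Z_series = MonitoringSeries(
        lake=spec.lake, variable="zooplankton", years=years, months=months,
        values=Z, units="mg/l",
    )
    # valid indices: those whose successor belongs to the same run
    has_successor = np.zeros(n, dtype=bool)
    has_successor[:-1] = ~new_run[1:]
    valid = np.flatnonzero(has_successor)
    rid = run_ids(P_series)[valid]
    g_true = DerivedSeries(
        variable="G", years=years[valid], months=months[valid],
        values=g_star[valid], run_ids=rid, params=spec.params,
    )
    f_true = DerivedSeries(
        variable="f", years=years[valid], months=months[valid],
        values=np.full(valid.size, spec.f_const), run_ids=rid, params=spec.params,
    )
    return P_series, Z_series, g_true, f_true


def inject_missing(series: MonitoringSeries, fraction: float, seed=None) -> MonitoringSeries:
    """Flag ``round(fraction·n)`` uniformly chosen samples as missing.

    Never removes the last observation of a calendar-month slice, so the
    result always satisfies the imputation precondition.
    """
    if not 0.0 <= fraction <= 0.2:
        raise ValidationError("fraction must lie in [0, 0.2]")
    n_flag = int(round(fraction * series.n))
    if n_flag == 0:
        return dataclasses.replace(series)
    rng = np.random.default_rng(seed)
    observed_per_month = {
        int(m): int(np.count_nonzero((series.months == m) & ~series.missing))
        for m in np.unique(series.months)
    }
    values = series.values.copy()
    flagged = 0
    for idx in rng.permutation(series.n):
        if flagged == n_flag:
            break
        if np.isnan(values[idx]):
            continue
        month = int(series.months[idx])
        if observed_per_month[month] <= 1:
            continue
        values[idx] = np.nan
        observed_per_month[month] -= 1
        flagged += 1
    if flagged < n_flag:
        warnings.warn(
            f"could only flag {flagged}/{n_flag} samples without emptying a month slice",
            stacklevel=2,
        )
    return dataclasses.replace(series, values=values)


def _with_obs_noise(series: MonitoringSeries, cv: float, seed) -> MonitoringSeries:
    rng = np.random.default_rng(seed)
    factors = np.exp(rng.normal(0.0, cv, size=series.n))
    return dataclasses.replace(series, values=series.values * factors)


def generate_dataset(spec: SimSpec) -> SimResult:
    """One full synthetic campaign: T, P, Z with missing values, plus truths."""
    temperature = generate_temperature(spec)
    P, Z, g_true, f_true = forward_simulate(spec)
    P_obs, Z_obs = P, Z
    if spec.obs_noise_cv > 0:
        P_obs = _with_obs_noise(P, spec.obs_noise_cv,
                                np.random.SeedSequence([spec.seed, _STREAM_OBSNOISE_P]))
        Z_obs = _with_obs_noise(Z, spec.obs_noise_cv,
                                np.random.SeedSequence([spec.seed, _STREAM_OBSNOISE_Z]))
    return SimResult(
        spec=spec,
        temperature=inject_missing(
            temperature, spec.missing_fraction,
            np.random.SeedSequence([spec.seed, _STREAM_MISSING_T]),
        ),
        phytoplankton=inject_missing(
            P_obs, spec.missing_fraction,
            np.random.SeedSequence([spec.seed, _STREAM_MISSING_P]),
        ),
        zooplankton=inject_missing(
            Z_obs, spec.missing_fraction,
            np.random.SeedSequence([spec.seed, _STREAM_MISSING_Z]),
        ),
        phytoplankton_full=P,
        zooplankton_full=Z,
        temperature_full=temperature,
        g_true=g_true,
        f_true=f_true,
    )
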