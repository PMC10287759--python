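# Methods

## The model and what is inverted

Lake monitoring programmes record phytoplankton abundance P, zooplankton
abundance Z and water temperature T monthly during the open-water season,
but never the phytoplankton growth rate itself.  planksync treats the
monitoring series as exact inputs to a discrete prey–predator model on the
monthly grid,

    ΔP(n)/P(n) = G(n) − f(n)·Z(n)
    ΔZ(n)/Z(n) = β·f(n)·P(n) − α,        ΔX(n) = X(n+1) − X(n),

and solves the two equations for the unknown functional terms at every time
step instead of prescribing them:

    G(n) = (β·ΔP(n) + ΔZ(n) + α·Z(n)) / (β·P(n))
    f(n) = (ΔZ(n)/Z(n) + α) / (β·P(n)).

G(n) is the intrinsic phytoplankton growth rate (month⁻¹; it may be
negative and is never clipped), f(n) the predation intensity.  The two
constants are α, the zooplankton decline rate unrelated to grazing
(month⁻¹, validated to [0, 20] by default), and β, the prey-to-predator
conversion efficiency (≈ 0.1 under Lindeman's 10% rule).  Because the
formulas are an exact algebraic rearrangement of the forward update, the
inversion is exact: applied to data generated by the forward model it
returns the prescribed growth signal to floating-point precision, which is
the package's central internal oracle (`G − f·Z = ΔP/P` holds identically).

Forward differences need a same-season successor.  A record is decomposed
into *season runs* — maximal blocks of consecutive calendar months — and
the step from the end of one season to the start of the next is dropped,
not bridged: no G or f value is attached to the last sample of a run.  A
"season" is any maximal consecutive-month run rather than a hard-coded
May–October window, so the code is agnostic to a campaign's actual
sampling months.

## Imputation

Missing values are filled before inversion by seasonal-split interpolation:
the series is split by calendar month (all Junes form one sub-series
ordered by year) and each missing value is linearly interpolated across
years inside its own month slice; a missing value outside its slice's
observed range takes the nearest observed value.  Consequences used as
test properties: observed values are never modified, the operation is
idempotent, and imputed values stay within the slice's observed min/max.
A month slice with no observation at all is an error rather than a guess.
Temperature gaps are treated identically.  No model-based (Kalman/ARIMA)
imputation is offered and imputed values carry no uncertainty.

## Phase, PLI and significance

The phase of an oscillation is anchored at its maxima: with t_k the k-th
detected maximum,

    φ(t) = 2π·(k + (t − t_k)/(t_{k+1} − t_k)),    t_k ≤ t ≤ t_{k+1},

i.e. linear interpolation of 2π·k through the maxima; φ is defined only
between the first and last maximum.  Maxima are detected by the simplest
deterministic rule — strict rise then non-rise (`x[i−1] < x[i] ≥ x[i+1]`),
first index of a plateau, endpoints excluded, no smoothing — documented so
that any reproduction difference is attributable.  A series with a single
maximum has well-defined maxima but no phase; detection alone only fails
when no interior maximum exists.

By default the time axis is the 0-based sample position, treating the
concatenated season runs as equally spaced steps; `phase(..., times=...)`
accepts a calendar coordinate instead, so the sensitivity of results to
stretching cycles across winter gaps can be checked.

Synchronization of two series on their common phase domain (N indices) is

    PLI = |(1/N) Σ_j exp(i·Δφ(j))| ∈ [0, 1],

1 iff Δφ is constant, with E[PLI²] = 1/N for i.i.d. uniform phase
differences — the analytic calibration the test suite checks by Monte
Carlo.  Δφ uses unwrapped phases; the unit phasor makes mod-2π reduction
immaterial.

Significance: each of n_surrogates (default 1000) surrogates independently
permutes the values of *both* series uniformly at random and re-runs the
entire pipeline (maxima → phase → PLI); shuffling only one series is
available as a mode switch.  A shuffle leaving fewer than two maxima is
re-drawn and counted.  The reported p is the percentage of surrogate PLIs
strictly below the observed one (ties count as not exceeded; they have
measure zero), and p ≥ 95% is read as phase-synchronized.  Each surrogate
consumes its own spawned NumPy child stream of a single seed, so results
are bit-reproducible and independent of evaluation order.

The non-parametric cross-check `rank_correlation` is Spearman's ρ via
scipy.

## Sensitivity sweep

`sensitivity.sweep` recomputes G and its temperature synchronization over a
grid of (α, β) — default α = 0..20 step 0.5 and β = 0.02..0.30 step 0.02, a
range covering the admissible α span and Lindeman-plausible β; the β grid
is an explicit assumption since no canonical bounds exist.  Every cell
derives its sub-seed from (seed, α-index, β-index), making the map
reproducible cell-by-cell.  Cells whose growth series has fewer than two
maxima are marked undefined and never synchronized.  `map_area` is the
fraction of synchronized cells; it supports qualitative comparisons of
region sizes between lakes, not absolute-area claims.

## Synthetic campaigns

`synthetic_data` emulates the statistical structure the analysis assumes:

- **Temperature** — T = temp_mean + temp_amplitude·sin(θ) + N(0, temp_noise_sd)
  with θ the seasonal angle (one cycle per season, peak mid-season), emitted
  only for in-season months.  Defaults: 20 years of 6-month seasons starting
  in May, 13 ± 7 °C, noise sd 1 °C — a realistic temperate-lake campaign.
- **Growth signal** — G* = growth_mean + growth_amplitude·sin(θ + lag) +
  N(0, growth_noise_sd); coupling is injected through the seasonal *phase*
  because the claim under study is phase locking, not amplitude correlation.
  Defaults 0.5 ± 0.3 month⁻¹, noise sd 0.05, lag 0.
- **Plankton** — the forward model P(n+1) = P(n)(1 + G* − f*·Z(n)),
  Z(n+1) = Z(n)(1 + β·f*·P(n) − α) with constant f* (default 1.0), α = 0.5,
  β = 0.1, restarting from (P0, Z0) = (5, 0.3) at every season start as a
  stand-in for unmodelled overwintering (a 12-month season has no gap and is
  simulated as one continuous run).  A step driving P or Z non-positive
  rejects the trajectory with a warning and fresh growth noise (up to 20
  redraws); a noiseless non-viable spec raises immediately.
- **Degradations** — a chosen fraction of samples (default 3%) is flagged
  missing, never the last observation of a month slice; optional
  multiplicative log-normal observation noise (obs_noise_cv) perturbs the
  *reported* abundances while the model trajectory remains the ground truth.

The matched uncoupled condition sets growth_amplitude = 0 with noise sd
0.15: the growth signal then carries no seasonal phase, which is the right
null for detection-power studies.  (Replacing temperature by an independent
realization would *not* be a null: two same-period seasonal series are
genuinely phase-locked.)

What the generator does not emulate: chaotic multi-annual plankton
variability, species succession, nutrient or light limitation, and
trends/regime shifts.  In particular, by default its raw phytoplankton
series is itself strongly seasonal and therefore phase-locks to
temperature — unlike real lake records, where P-vs-T locking can be absent
even when G-vs-T locking is present.  Passing tests on synthetic data
therefore validate the machinery (exactness of the inversion, calibration
and power of the surrogate test), not field conclusions about any real
lake.

## Numerical and design choices

- CSV dialect: header `year,month,value`, missing = empty or `NA`
  (case-insensitive); derived series add `run_id`.  Floats are written with
  `repr`, so read ∘ write is lossless.
- Abundances must be > 0 where observed (they enter denominators);
  temperature is unrestricted.
- All randomness flows from integer seeds through `numpy.random.SeedSequence`
  spawning; no global RNG state is touched.
- Problem sizes in the shipped analyses: 20-year campaigns (120 samples),
  200–1000 surrogates per test, 200 seeds per detection-rate estimate, and a
  21×8 (α, β) grid at 200 surrogates in the acceptance script — small enough
  to run in seconds to minutes on one core while leaving Monte-Carlo errors
  well inside the asserted tolerances.

## Known limitations

- The inversion inherits observation error unfiltered: G(n) is exact only
  for exact P, Z.  Imputed or noisy samples propagate directly into G.
- Maxima detection on raw series is sensitive to plateaus produced by
  coarse rounding; no smoothing is applied by default.
- Units of P and Z are taken as given; the model does not reconcile biomass
  vs count units, which only rescales f and the effective β.
- No fitting of α, β to data is provided — the constants are swept, not
  estimated.
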