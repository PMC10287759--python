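# planksync

Phytoplankton growth rates are not measured by lake monitoring programmes —
only abundances and temperature are.  planksync recovers the growth-rate
series from monthly phytoplankton (P) and zooplankton (Z) monitoring data by
inserting the series directly into a discrete prey–predator model and
solving for the unknown growth term,

    G(n) = (β·ΔP(n) + ΔZ(n) + α·Z(n)) / (β·P(n)),      ΔX(n) = X(n+1) − X(n),

where α (month⁻¹) is the zooplankton decline rate unrelated to grazing and
β ≈ 0.1 the prey-to-predator conversion efficiency.  It then asks whether
the recovered G(n) oscillations are phase-locked to water temperature: the
phase φ(t) = 2π(k + (t − t_k)/(t_{k+1} − t_k)) is interpolated between
detected maxima t_k, the phase-locking index PLI = |⟨exp(i·Δφ)⟩| ∈ [0, 1]
is computed on the common phase domain, and its significance p is the
percentile of the observed PLI in a null distribution from random shuffles
of both series (p ≥ 95% read as synchronized).  A sensitivity sweep maps the
(α, β) region where synchronization holds.  The package is aimed at
ecologists analysing seasonal monitoring series with winter gaps; a
synthetic-data generator with known ground truth makes every stage testable
without any field data.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
20-year campaign (6-month seasons, growth coupled to the seasonal
temperature phase):

```text
$ python analysis/01_simulate.py
simulated 120 monthly samples over 20 years (6-month seasons), 12 values missing
alpha=0.5 beta=0.1 growth coupled to the seasonal temperature phase (lag 0.0 rad)

$ python analysis/02_impute.py
phytoplankton: 4 of 120 values imputed -> phytoplankton_imputed.csv
...

$ python analysis/03_invert_growth.py
recovered 100 growth-rate values (alpha=0.5, beta=0.1) -> results/growth_rate.csv
vs ground truth: median abs error 1.11e-16, max 0.1517 (nonzero only where imputation filled a gap)

$ python analysis/04_phase_sync.py
growth_vs_temperature: PLI=0.948 (N=96), p=100.0% -> synchronized
phytoplankton_vs_temperature: PLI=1.000 (N=109), p=100.0% -> synchronized

$ python analysis/05_sensitivity_sweep.py
615 of 615 (alpha, beta) cells synchronized (area fraction 1.000) -> results/sync_map.csv
```

Reading the output: the inversion reproduces the generator's prescribed
growth signal exactly wherever the data are observed (median error at
machine precision; the max reflects the 4 imputed samples), and the
recovered G(n) locks to temperature — its PLI of 0.948 over N = 96 common
phase points exceeds all 1000 shuffle surrogates (p = 100%).  On this
synthetic campaign the raw phytoplankton series is also seasonal and locks
too; on real lake data that second verdict is typically negative, which is
exactly what the method is designed to discriminate.  `analysis/06_real_data.py`
runs the per-lake analysis at published settings when monitoring CSVs are
available.

The same stages are exposed as a CLI (`planksync simulate|impute|growth|pli|sweep|run`),
e.g. `planksync run --config config.yaml` for an end-to-end, seed-reproducible run.

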