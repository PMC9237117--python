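# bloomtrace

Backward Lagrangian tracing of cyanobacteria bloom origins in a marginal
sea, for marine ecologists and ocean modellers who want to compare the
environmental *history* of bloom-forming surface water with water that did
not bloom — rather than the conditions during the bloom itself.

## The method

A satellite bloom classification gives, for one event date, a three-state
raster: bloom / no-bloom / inconclusive. bloomtrace seeds virtual drifters
uniformly at random in the study box (default 13–24°E, 54–60°N, 4000
drifters), labels each by its seed pixel (inconclusive pixels are
discarded), and integrates every drifter backward in time through archived
surface velocities with an explicit Euler scheme,

    Δλ = −u·Δt/(R cos φ)·180/π,   Δφ = −v·Δt/R·180/π,

default Δt = 3 h over a 60-day window, velocities interpolated bilinearly
in space (land-masked, renormalised weights) and linearly in time. Each
trajectory point is then linked to sea-surface temperature, mixed-layer
depth H, distance to coast, and mixed-layer averaged photosynthetically
active radiation

    PAR = f·I0·(1 − e^(−kH))/(kH),   f = 0.42,  k = 0.2 m⁻¹,

where I0 is incoming shortwave. Two contrasts come out:

* **trajectory ensembles** — per-offset means ± standard deviations of
  each variable for bloom vs. no-bloom parcels, and the offshore-exposure
  statistic: the distance D that 90% of bloom parcels never undercut in
  the final 3 weeks;
* **nutrient climatology** — surface bottle data zoned into coastal
  (< 40 nm) and offshore (> 60 nm) records, binned May–September, with
  box-whisker summaries (1.5·IQR outlier fence) of nitrate, phosphate and
  excess phosphate P* = PO₄ − NO₃/16.

A synthetic-scenario generator produces every input — rimmed-basin grids,
analytic flows (uniform / solid rotation / double gyre), smooth forcing,
bloom masks confined beyond a designed offshore distance, and nutrient
tables with a designed coastal enrichment — so the whole chain is testable
against known truth. See `docs/methods.md` for the model details and
design choices.

## Worked example

```python
import numpy as np
import bloomtrace as bt

scenario = bt.generate_scenario(bt.ScenarioConfig(rng_seed=0))

seeds = bt.seed_random(bt.SeedingConfig(rng_seed=0), scenario.grid)
labels = bt.classify_drifters(seeds, scenario.bloom_mask)
print("drifters:", np.bincount(labels, minlength=3))  # no_bloom, bloom, discarded

traj = bt.advect_backward(seeds, scenario.u, scenario.v,
                          scenario.t_event, bt.TrackerConfig(), labels=labels)
hist = bt.sample_environment(traj, scenario.sst, scenario.mld,
                             scenario.swr, scenario.dist_field)

summary = bt.group_statistics(hist, "sst")
print("SST at event, bloom vs no-bloom: "
      f"{summary.mean_bloom[0]:.2f} vs {summary.mean_nonbloom[0]:.2f} degC")

d90 = bt.offshore_exposure(hist, window_days=21.0, coverage=0.90)
print(f"90% of bloom parcels stay beyond {d90:.1f} nm offshore "
      "in the 3 weeks before the event")

clim = bt.monthly_whisker_stats(scenario.nutrients, scenario.grid,
                                scenario.dist_field)
july = clim[(clim.month == 7) & (clim.variable == "po4")]
print(july[["zone", "median", "q25", "q75", "n_used", "n_outliers"]]
      .to_string(index=False))
```

prints

```
drifters: [2134 1469  397]
SST at event, bloom vs no-bloom: 16.02 vs 15.99 degC
90% of bloom parcels stay beyond 23.9 nm offshore in the 3 weeks before the event
    zone  median  q25  q75  n_used  n_outliers
 coastal    0.41 0.33 0.50     767          10
offshore    0.30 0.24 0.36     866          21
```

Reading it: of 4000 seeded drifters, 1469 sat in bloom pixels, 2134 in
no-bloom pixels, and 397 over inconclusive (cloud-proxy) pixels were
discarded. SST histories of the two groups are nearly indistinguishable,
but the bloom ensemble is strongly confined offshore — the 90% exposure
distance of 23.9 nm exceeds the 15 nm confinement designed into the
scenario's bloom mask, recovered here from the traced histories. The July
phosphate climatology shows the designed coastal enrichment: coastal
median 0.41 vs. offshore 0.30 µmol L⁻¹.

The same workflow is available from the shell:

```sh
bloomtrace simulate --out data/ --seed 0
bloomtrace seed  --mask data/bloom_mask.nc --n 4000 --seed 0 --out data/seeds.csv
bloomtrace trace --fields data/fields.nc --seeds data/seeds.csv \
                 --event-time 5270400 --window-days 60 --dt-hours 3 \
                 --out data/traj.csv
bloomtrace env   --traj data/traj.csv --fields data/fields.nc \
                 --event-time 5270400 --out data/env.csv
bloomtrace stats --env data/env.csv --var sst --out data/sst_summary.csv
bloomtrace nutrients --table data/nutrients.csv --grid data/fields.nc \
                     --out data/climatology.csv
```

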