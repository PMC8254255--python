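# emsloc

Ambulance station location toolkit for tiered (ALS/BLS) emergency medical
services in mixed urban–rural regions. It combines:

- **demand** — annual EMS and high-priority (FHQ) demand per municipality
  from age-group incident rates (per-1,000 rates for ages 0–14, 15–64, 65+)
  plus the aging index;
- **travel** — deterministic travel times on a categorized road network
  with speeds by road class, urban/rural location, driving mode
  (lights & sirens vs standard) and time-of-day regime; shortest-path
  `t_ij` matrices and coverage neighbourhoods `N_j` (default 7 min);
- **optimize** — three MILP siting models on scipy's HiGHS backend:
  expected-coverage maximization with busy-fraction discounting (MEXCLP),
  the weighted p-median (optionally under a lexicographic coverage floor),
  and a hierarchical two-tier median that picks the `r` ALS sites among
  the `p` opened stations; plus fixed-station preprocessing, a
  kernel-search matheuristic for large instances and post-hoc ALS
  allocation;
- **simulate** — a discrete-event EMS simulator: non-homogeneous Poisson
  arrivals shaped by a 24-hour profile, population-proportional call
  placement, closest-unit dispatch with concurrent ALS dispatch to
  high-priority calls, redirection of returning units, crew-dependent
  hospital-transport decisions (77% paramedic-only / 51% physician-present),
  Erlang drop-off times, and the seven standard performance indicators
  with replication confidence intervals;
- **driver** — the recursive optimize↔simulate loop with busy-fraction
  feedback and a model-comparison harness on common random numbers;
- **survival** — a logistic survival-probability curve translating
  response-time reductions into percentage-point gains and expected
  additional survivors;
- **fixtures** — a seeded synthetic-region generator (connected road
  network, age-structured populations, stations, hospitals, population
  grid) with lossless CSV/GraphML round-trip I/O and deterministic call
  scripts, so everything is testable without external data.

## CLI

```sh
emsloc generate --seed 5 --out region/          # synthetic region files
emsloc optimize --region region/ --model hierarchical --out solution.json
emsloc simulate --region region/ --stations solution.json \
                --replications 10 --days 91 --seed 1 --out report.json
emsloc iterate  --region region/ --model pmp --max-iters 10 --seed 1
emsloc compare  --region region/ --seed 1      # current vs optimized layouts
emsloc survival --t0 11.37 --reduction-s 56 --n-patients 26003
```

`generate` accepts `--spec spec.toml` with any `RegionSpec` field
(`n_municipalities`, `urban_fraction`, `n_current_stations`,
`als_fraction`, `n_hospitals`, `grid_resolution`, `network_style`, ...).

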