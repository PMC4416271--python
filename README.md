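# nasocond

A two-airway nasal air-conditioning model: transient heat and water-vapour
transport over segmented nasal geometry, laminar resistance-network
partitioning of tidal airflow between the two passages, and an
airway-surface-liquid (ASL) water-equivalent-height hydration ledger. The
model demonstrates the functional asymmetry of patent vs. congested
passages: the side carrying the larger flow share does the bulk of the
air-conditioning work and dehydrates its anterior ASL during inhalation,
while the congested side stays hydrated; swapping the congestion pair swaps
the roles.

## What's inside

| module | role |
|---|---|
| `nasocond.psychro` | moist-air properties: Magnus saturation vapour density, absolute humidity, dry-air transport properties |
| `nasocond.geometry` | per-slice area/perimeter lumps, CSV I/O, synthetic narrow-gap geometry with per-side congestion |
| `nasocond.airflow` | parallel-plate laminar resistance network (f = 24/Re, Darcy–Weisbach), partitioning ratios, tidal waveform |
| `nasocond.asl` | hydration ledger: water-equivalent height, supply/reabsorption caps, gel-on-brush layer heights, dehydration metrics |
| `nasocond.transport` | explicit upwind/forward-Euler solver for per-segment air temperature and vapour concentration, coupled to the ledger |
| `nasocond.runner` | YAML configuration, orchestration, tidy CSV/JSON outputs, the nasal-cycle swap experiment |

## CLI

```sh
# one simulation (defaults: 120 slices/side, 500 mL at 12 breaths/min,
# ambient 23 °C / 45% RH, wall 32→37 °C)
nasocond simulate --config config.yaml --out out_dir

# synthetic geometry CSV
nasocond synth-geometry --out geom.csv --congestion-right 0.3

# congestion pair + swapped pair, with a role-swap comparison
nasocond cycle-experiment --config config.yaml --out cycle_dir
```

`simulate` writes `results.csv` (`side,k,x_over_l,time_s,t_air_c,
c_air_kg_m3,he_um`), `asl_timeseries.csv`, `geometry.csv`, a `summary.json`
(partition ratios, dehydration metrics, per-phase extrema, conservation
audits) and `run.log`. Configuration keys mirror
`nasocond.runner.SimulationConfig`; any subset may be given in the YAML.

Note on the supply cap: the ledger's default maximal mucosal supply is the
printed 7.9 g/cm²·hr, which refills the whole ASL in well under a second, so
with defaults the ASL never dehydrates. The cap is carried as a
`(value, unit)` pair — pass e.g. `asl: {supply_max: [7.9, "mg/cm2/hr"]}` to
see dehydration dynamics.

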