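# wardflow

Dynamic nonlinear network-flow modelling of patient flow through a hospital
ward network.

A hospital is represented as a directed graph: wards are vertices with a bed
capacity, a staff (server) count and a service-time distribution fitted from
observed lengths of stay; care pathways are edges with a waiting-queue
capacity and a distribution probability (the fraction of patients taking
that route). The engine iterates over an hourly arrival-rate profile and,
at each step:

1. samples a service time per ward (rejection-sampled into the observed
   LOS range),
2. adjusts every vertex capacity from its flow intensity
   (arrival rate / service rate) via the overflow ratio rho/(1-rho), and
   every edge capacity by subtracting its inflow (arrival rate x
   distribution probability),
3. sums the adjusted edge and target-vertex terms into a static residual
   graph,
4. finds augmenting source-to-sink paths by depth-first search over
   strictly positive residuals and pushes **forward-only** flow (no
   backward residual edges — patients do not take alternative pathways),
5. folds the post-augmentation residuals into two run-long records: the
   per-edge min/max residual graph (bottleneck persistency / severity /
   overflow) and the per-ward residual time series (dynamic ward
   behaviour).

Diagnostics derived from a run: persistency (max-min), severity (0-max)
and overflow (0-min) edge matrices, blockage coloring (wards never visited
by any augmenting path), outlier-filtered ward time series, and k-hop
root-cause traces around a focal ward.

Residual capacities are real-valued and may be negative: a negative value
measures overflow intensity, not a patient count.

## CLI

```sh
# write a synthetic hospital (fixed 20-ward fixture) + arrival tables
wardflow generate --out data/ --toy

# check the input tables
wardflow validate --wards data/wards.csv --edges data/edges.csv

# run the simulation: 24-hour spike profile, seeded, constant 5.01 h service
wardflow run --wards data/wards.csv --edges data/edges.csv \
             --los data/los.csv --arrivals data/arrivals.csv \
             --out results/run1 --seed 1 --constant-service 5.01

# a 1-week horizon with equalized distribution probabilities
wardflow run ... --repeat 7 --equal-dp

# diagnostics: matrices, blockage coloring, time series, root causes
wardflow report results/run1 --ward "Emergency Department" --depth 3
```

`run` accepts a YAML config via `--config run.yaml`; any key can be
overridden by the matching flag. Every run directory is self-describing
(manifest with seed + config hash, GraphML copy of the network, CSV/JSONL
result tables) and reruns are bit-identical.

Input schemas (CSV or TSV, header required):

| table    | columns                                |
|----------|----------------------------------------|
| wards    | `ward,beds,staff` (blank staff ⇒ beds) |
| edges    | `source,target,capacity,probability`   |
| LOS      | `ward,los_hours` (one row per stay)    |
| arrivals | `hour,rate` or a plain one-column list |

## Package layout

- `wardflow.network_model` — ward/pathway types, tabular loading,
  validation, equal-distribution transform, GraphML/DOT export
- `wardflow.service_time` — bounded service-time distributions
  (lognormal / truncated-normal / uniform / constant) with rejection
  sampling
- `wardflow.capacity_adjust` — service rate, flow intensity, overflow
  ratio, vertex/edge capacity adjustment, static residual graph
- `wardflow.flow_engine` — DFS path search, forward-only augmentation,
  the per-step loop and run-long records
- `wardflow.diagnostics` — persistency/severity/overflow matrices,
  blockage coloring, time-series filtering, root-cause tracing
- `wardflow.synthetic_hospital` — the fixed 20-ward/62-edge fixture, the
  24-hour spike arrival profile, seeded random network generation
- `wardflow.cli` — `generate | validate | run | report`
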