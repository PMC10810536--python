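# netctrl

Target-controllability analysis of signed, directed effective-connectivity
(EC) networks modelled as linear dynamical systems `x' = A x + B u`.

The package provides, end to end:

- **Synthetic cohorts** (`netctrl.connectome`): stable (Hurwitz) signed
  asymmetric coupling matrices with configurable link density, excitatory
  fraction and inter-subject similarity (calibrated by bisection), node
  metadata with resting-state-network labels and pseudo-anatomical
  coordinates, model-implied functional connectivity from the stationary
  covariance, impulse-response simulation, multiplicative-noise
  perturbations and node-accessibility sampling.
- **Control machinery** (`netctrl.gramian`): infinite-horizon
  controllability/observability Gramians via continuous Lyapunov solves,
  target-projected Gramians, worst-case energies (`1/lambda_min` with a
  practical-controllability threshold of 1e-12), all pairwise
  single-driver/single-target energies in n Lyapunov solves, finite-horizon
  Gramians, minimum-energy input synthesis and exact-exponential controlled
  simulation.
- **Centralities** (`netctrl.centrality`): absolute in/out strength and
  their ratio, PageRank on the binarized digraph, Gramian-trace (pq)
  control centrality with exact squared-accessibility scaling, driver/target
  energy centralities, inverse-weight shortest paths and propagator
  coupling.
- **Driver selection** (`netctrl.selection`): deterministic rankings with an
  explicit tie rule, target-excluded driver selection, random baselines and
  z-scores, per-target-set optimal-centrality identification, mean-rank
  aggregation across subjects, Fisher-exact RSN enrichment with
  Benjamini–Hochberg correction and top-k ranking overlap.
- **Experiments** (`netctrl.experiments`): energy scaling versus driver and
  target counts, pairwise-energy correlates, hub/consistency analyses,
  per-RSN control tables (individual versus aggregated rankings, including
  an FC-based variant), enrichment matrices, perturbation sensitivity,
  accessibility experiments and a `run_all` orchestrator writing TSV tables
  plus JSON metadata.

## Command-line interface

```sh
netctrl generate --seed 1 --out-dir cohort/          # synthetic cohort
netctrl energy cohort/ --out-dir out/                # pairwise energies
netctrl centrality cohort/ --out-dir out/            # per-node centralities
netctrl select cohort/ --centrality out_strength --n-drivers 10 \
    --target-rsn DMN --out-dir out/
netctrl rsn cohort/ --out-dir out/                   # per-RSN control table
netctrl sensitivity cohort/ --out-dir out/
netctrl accessibility cohort/ --out-dir out/
netctrl run-all cohort/ --seed 1 --out-dir report/   # everything
```

A cohort directory holds `nodes.tsv` (node metadata), one
`<subject>.ec.tsv` per subject (dense TSV matrix, row i / column j = signed
influence of node j on node i) and `generator_config.json`.
`--config` accepts a JSON or YAML file overriding generator or experiment
parameters.

## Library example

```python
import netctrl as nc

cohort = nc.generate_cohort(nc.GeneratorConfig(n_subjects=5, seed=1))
ec = cohort.subjects[0]

pe = nc.pairwise_energies(ec)                 # E[i, j]: drive j from i
driver_e, target_e = nc.energy_centralities(pe)

targets = nc.TargetSet(tuple(cohort.nodes.indices_of("DMN")))
ranking = nc.rank_nodes(driver_e, "ascending")
drivers = nc.select_drivers(ranking, 10, exclude=targets)
g = nc.target_gramian(nc.controllability_gramian(ec, drivers), targets)
print(nc.worst_case_energy(g).log10_energy)
```
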