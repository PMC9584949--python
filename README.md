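# clonaldyn

Clonal dynamics of p53-mutant progenitors in squamous epithelium:
simulation, estimation, and sequencing-based readouts, exercisable
end-to-end on seeded synthetic data.

Normal oesophageal epithelium is maintained by a single population of
basal progenitors whose divisions produce two progenitors (PP), one of
each (PD), or two differentiating cells (DD) with probabilities
r(1+δ) / 1−2r / r(1−δ). Balanced fates (δ = 0) give homeostasis and
neutral clone drift; a heterozygous p53 mutation acts as a fate
imbalance δ > 0 that drives exponential clonal expansion of the mutant
population at rate 2rλδ per week (λ = division rate). This package
implements, for that system:

* **`progenitor_ca`** — a stochastic cellular automaton of the basal
  layer on a periodic hexagonal lattice (default 10,000 sites), with
  transient double occupancy, migration/extrusion resolution, and a
  crowding feedback that suppresses the mutant fate bias next to
  doubly occupied sites.
* **`branching`** — the non-spatial branching-process form of the same
  model: an exact, vectorized Gillespie sampler plus a master-equation
  integrator used as an independent oracle.
* **`fate_regression`** — estimation of δ from clone sizes: a
  statsmodels-style model whose `fit()` inverts the slope of
  ln(mean clone size) vs time through δ̂ = slope/(2rλ).
* **`lineage_stats`** — clone censuses of simulated trajectories
  (survivor counts, size distributions, labelled fraction, density).
* **`clone_genomics`** — estimators over gridded-biopsy deep-sequencing
  mutation tables: merging of clones shared between samples closer than
  3 mm, clone-area bounds (VAF to 2×VAF), per-gene tissue coverage,
  synonymous mutation burden per Mb, clone density, and TP53
  consequence ranking.
* **`cna`** — copy-number calling from shallow matched coverage: bait-
  aware off-target binning, logR, GC-wave correction, exact penalized
  change-point segmentation, single-copy cell-fraction estimates, and
  the ≥10%-cells / ≥20-Mb post-hoc filters.
* **`synthetic`** — seeded generators for biopsy grids with planted
  clones and matched binned read sets with planted gains/losses,
  including truth tables for scoring.

See `docs/methods.md` for the models, conventions and design decisions.

## Worked example: recovering the fate imbalance

Simulate 20,000 clones under one published parameter set for mouse
oesophagus (r = 0.06, λ = 2.9/week, Γ = 3.7/week, δ = 0.32) and invert
the growth of the mean clone size with another published set's rates
(r = 0.1, λ = 1.9/week):

```python
import numpy as np
from clonaldyn import PUBLISHED_PARAMS, simulate_clones, estimate_delta

times = np.arange(0.0, 25.0)                       # weekly, 24 weeks
P, D = simulate_clones(PUBLISHED_PARAMS[1], times, 20_000, seed=42)
mean_size = (P + D).mean(axis=0)                   # basal cells per induced clone
res = estimate_delta(mean_size, times, r=0.1, lam=1.9, window=(4, 24))
print(res.summary())
```

```
Fate-imbalance regression: ln(mean clone size) ~ time
  window          : 4 - 24 weeks  (21 points)
  slope           : 0.1109 /week  (se 0.0001)
  intercept       : 0.5488
  known r, lambda : 0.1, 1.9 /week
  delta_hat       : 0.2919  (se 0.0004)
```

The fitted slope (0.111/week) is the clone growth rate 2rλδ of the
simulated parameters; dividing by 2rλ of the *other* parameter set
returns that set's imbalance, δ̂ ≈ 0.29 — the published parameter
combinations are interchangeable because they encode the same growth
rate. The intercept exceeds 0 because by week 4 each surviving lineage
carries its equilibrated differentiating compartment.

## Command line

The same functionality is exposed as an umbrella CLI:

```sh
clonaldyn simulate --mut-delta 0.29 --duration 52 --out-dir runs/mut
clonaldyn estimate-delta mean_sizes.tsv --r 0.1 --lam 1.9
clonaldyn merge-clones grid_mutations.tsv --threshold 3
clonaldyn burden grid_mutations.tsv --panel panel.tsv
clonaldyn cna-call --sample-bins s.tsv --control-bins c.tsv --mode targeted --baits baits.bed
clonaldyn synth grid|cna|tracing ...
```

Every run writes a JSON manifest (parameters, seed, input hashes) next
to its outputs.

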