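# cellblocks

Nested stochastic block model (nSBM) clustering for single-cell kNN graphs.

Standard single-cell clustering optimises modularity with a resolution
parameter, which finds "communities" even in pure noise and does not encode
a real hierarchy. `cellblocks` instead treats the cell neighbourhood graph
as a draw from a generative model — the microcanonical degree-corrected
stochastic block model — and picks the partition hierarchy that minimises
the description length

    Σ = −ln P(A | θ, b) − ln P(θ, b)      [nats]

where *A* is the observed cell graph, *b* the nested partition and
θ = (block edge-count matrices *e*, degree sequence *k*).  Because Σ is a
proper model-selection criterion, a random graph yields **one** block
rather than spurious clusters, and the number of groups needs no tuning
knob.  The package provides:

* preprocessing from raw counts to a kNN cell graph (filter, total-count
  normalise + log1p, PCA, union-symmetrised kNN), plus the two perturbation
  operators used to probe null behaviour (degree-preserving edge shuffling,
  per-gene white-noise injection at multiplier *k* of the gene-wise σ);
* exact evaluation of the nested description length and of single-move
  deltas; the assortative planted-partition objective (PPBM) as a
  resolution-free alternative;
* ensemble minimisation (agglomerative ladder + merge-split MCMC, 100
  restarts by default) and a consensus over the ensemble with per-cell
  marginal block probabilities;
* cell stability (fraction of non-root levels where a cell's max marginal
  exceeds 1 − 1/B), entropy-based cell affinities and label transfer with
  an "Unknown" rejection state, and hierarchy-level selection via
  Tracy–Widom eigenvalue counting (k̂) or maximum |modularity|.

## Worked example

```python
import numpy as np
from cellblocks import (FitConfig, PlantedSpec, generate_sbm_graph,
                        minimize_nested, build_consensus, cell_stability,
                        adjusted_rand_index)

# a 4-block assortative graph, 400 cells, within/between ratio 10
g, truth = generate_sbm_graph(PlantedSpec(400, [100]*4, 0.2, 0.02, seed=1))
states = minimize_nested(g, FitConfig(n_init=5, seed=1))
best = states[0]
print(best.block_counts)                 # [4, 1]
print(round(best.sigma, 1))              # 17322.0 nats
cons = build_consensus(states, seed=1)
print(adjusted_rand_index(cons.labels[0], truth))   # 1.0
print(float(cell_stability(cons).mean()))           # 1.0
```

The fitted hierarchy has four level-0 blocks under a single root; the
consensus over five restarts reproduces the planted partition exactly
(ARI = 1.0) and every cell is stably assigned (mean S = 1.0).  On an
Erdős–Rényi graph of the same size the same call returns
`block_counts == [1]`: no structure, no clusters.

A command-line interface mirrors the library:

```bash
cellblocks simulate --blocks 100,100,100,100 --p-in 0.2 --p-out 0.02 --outdir sim/
cellblocks fit --graph sim/graph.tsv --n-init 5 --seed 1 --outdir fit/
cellblocks select-level --graph sim/graph.tsv \
    --partition fit/best_partition.json --method modularity --outdir sel/
```

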