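# Methods

## Model

`cellblocks` fits the microcanonical degree-corrected stochastic block
model (DC-SBM) and its nested extension to an undirected simple graph over
cells. A partition hierarchy `b = (b_0, …, b_L)` assigns cells to blocks at
level 0 and blocks to super-blocks above, ending in a single root. The
fitted score is the description length in nats,

    Σ = −ln P(A | θ, b) − ln P(θ, b),

with the following exact ingredients (all frozen by enumeration-based unit
tests, so any change to the formulas is detected):

* **Level-0 likelihood (degree-corrected).** The configuration-count form

      −ln P(A | k, e, b) = −[ Σ_{r<s} ln e_rs! + Σ_r ln e_rr!!
                              + Σ_i ln k_i! − Σ_r ln e_r! ],

  where `e_rs` counts edges between blocks r and s, the diagonal stores
  twice the internal count (so `Σ_rs e_rs = 2E`), and `e_r` is the total
  degree of block r. This counts multigraph configurations; for the simple
  graphs produced by kNN construction it is the standard approximation used
  by microcanonical SBM implementations. A non-degree-corrected variant
  (binomial counts over possible edge slots) is available behind the
  `degree_corrected` flag.
* **Degree prior (uniform hyperprior).** Per block,
  `ln n_r! − Σ_k ln η_rk! + ln q(e_r, n_r)`, with `η_rk` the number of
  degree-k cells in block r and `q(m, n)` the number of partitions of the
  integer m into at most n parts. `q` is tabulated once per graph with the
  recurrence `q(m, n) = q(m, n−1) + q(m−n, n)` evaluated in log space
  (`logaddexp` running sums), so arbitrarily large degree totals are safe.
* **Partition prior, per level.**
  `ln n! − Σ_r ln n_r! + ln C(n−1, B−1) + ln n` — uniform over size
  compositions, assignments given sizes, and the number of blocks.
* **Upper levels.** Each level l ≥ 1 describes the block multigraph
  `e_{l−1}` with a non-degree-corrected multigraph SBM whose edge counts
  are priced by multiset coefficients:
  `U(l) = Σ_{R<S} ln ((m_R m_S, e_RS)) + Σ_R ln ((m_R(m_R+1)/2, e_RR/2))`,
  where `m_R` counts the level-(l−1) blocks inside R. The root's own 1×1
  matrix is the total edge count, a constant of the data, and carries no
  term. A flat model is therefore exactly a two-level hierarchy, and its
  closure terms are `ln B + ln ((B(B+1)/2, E))`.
* **Planted-partition objective (PPBM).** The assortative constraint keeps
  one internal edge budget per block and a single global between-block
  budget `e_out` spread uniformly over the B(B−1)/2 pairs:

      −ln P(A|k,e,b) = −[ Σ_r ln e_rr!! + Σ_i ln k_i! + ln e_out!
                          − Σ_r ln e_r! − e_out ln(B(B−1)/2) ],

  with prior `ln(E+1) + ln ((B, e_in))` on the budget split and the same
  degree and partition priors. At B = 1 the likelihood reduces to the
  one-block DC-SBM. This removes the resolution parameter: assortative
  structure is kept only when it compresses the graph.

No claim of bit-equality with graph-tool is made; the prior flavour above
is one standard choice within the microcanonical family and is documented
and frozen here.

## Inference

Each restart of the minimiser runs:

1. **Agglomerative ladder.** From singletons (or a random 2048-block
   partition for very large graphs), the number of blocks is driven down a
   fixed halving schedule by *forced* merges — the least-cost candidate
   merges are applied even when their delta is positive, because single
   merges out of an unstructured partition are almost always uphill even
   when the merged scale is globally better. At every rung the partition is
   refined by greedy node-move sweeps (no merges: improving merges from an
   unstructured state cascade straight to one block, skipping the scales
   the ladder exists to visit) and the best Σ seen anywhere on the ladder
   is recorded.
2. **Polish.** From the best rung: optional stochastic single-node
   Metropolis–Hastings sweeps at inverse temperature β (default 1; they
   diversify the ensemble across restarts), then greedy sweeps interleaved
   with strictly improving merge passes until `patience` sweeps bring no
   improvement above 1e−8 nats.
3. **Hierarchy.** The block multigraph of the fitted level is grouped with
   the multiset objective by the same ladder, recursively, until a level
   returns a single block (or fails to coarsen, in which case the root is
   attached directly). A final alternating pass of greedy node-move sweeps
   over all levels uses the exact nested deltas.

Restart i uses seed `base_seed + i`; restarts are independent, so results
are identical whether they run serially or concurrently. The hot flat-level
kernel is numba-compiled; the nested state, its exact deltas and the
`mcmc_sweep` operation (single-node moves, merges, random-bisection splits
with documented proposal probabilities) are pure Python and are
cross-checked against the kernel to 1e−9 in the tests. Move deltas follow
the generic local-terms path; moves that create or empty a block cascade
structurally through the hierarchy and fall back to an exact
recompute-on-copy.

`FitConfig` defaults: `n_init=100` restarts (matching common ensemble
practice for this model family), `max_sweeps=200`, `patience=10`,
`beta=1`. The statistical tests and the acceptance script use `n_init`
2–5, `max_sweeps=60`, `patience=5` — at the simulated sizes (400–600
cells) individual restarts already converge, and the smaller ensembles
are the package's chosen study sizes for those experiments.

## Consensus and scores

All models are projected to cell level at each depth, aligned to the
best-Σ model by Hungarian maximum-overlap matching (unmatched blocks get
fresh labels), and the marginal `M_l[c, r]` is the fraction of models
placing cell c in aligned block r. Consensus labels are the per-row argmax
(ties to the smaller index); `nested_labels` re-maps the level-0 consensus
through the best model's hierarchy so labels nest across levels by
construction. Note that max-overlap alignment biases individual aligned
rows toward the reference by O(√(B/n_cells)); the uniform-randomness
contract (marginals → 1/B) therefore holds exactly for column means and to
±0.05 for the bulk (95%) of entries at 1000 models, which is how it is
tested.

**Cell stability** is the fraction of levels with B ≥ 2 at which a cell's
maximum marginal strictly exceeds 1 − 1/B; uniform rows score 0, certain
rows 1.

**Cell affinity and transfer.** Given any labelling of the graph
(including an "Unknown" block), the change ΔΣ of moving one cell into each
block is evaluated exactly on the flat DC-SBM; a row's affinity is
softmax(−ΔΣ), so the argmax is normalisation-independent. Label transfer
reassigns only "Unknown" cells, each to its argmax label, iterated to a
fixed point (cap 20 rounds): a coherent sub-cluster of query cells
otherwise props up its own "Unknown" block and holds its members back,
while cells without evidence — isolated nodes in particular — keep
rejecting every annotated label at every round (for a degree-0 cell the
only non-zero terms are the degree-histogram and block-size priors, which
favour the block already holding the other zero-degree cells).
`max_iter=1` recovers the single-shot assignment.

**Level selection.** `rmt_khat` standardises genes (zero mean, unit sample
variance; constant genes dropped with a warning), takes the eigenvalues of
Z'Z and counts those whose statistic `(λ − μ)/σ` with
μ = (√(n−1) + √p)² and σ = √μ·(1/√(n−1) + 1/√p)^(1/3) exceeds the upper
Tracy–Widom (β=1) quantile; the embedded quantile table holds the standard
thresholds 0.9793 / 2.0234 / 3.2724 for α = 0.05 / 0.01 / 0.001. The
selected level minimises |B_x − k̂|; ties go to the coarser level (fewer
groups are easier to validate). The alternative selects the level of
maximum |Q| (Newman modularity, γ = 1), same tie rule. Note that m groups
with distinct centroids span an (m−1)-dimensional subspace after
centering, so k̂ typically reads m−1 on cleanly separated data.

## Synthetic data

`generate_sbm_graph` draws Bernoulli edges with within-block probability
`p_in`, across-macro probability `p_out`, and — for nested designs — the
geometric mean √(p_in·p_out) between sibling micro-blocks. Degree
heterogeneity enters through Pareto propensities θ = (1−U)^(−s) (s = 0
homogeneous), normalised to unit mean and capped at edge probability 1.
`generate_expression` gives each gene a log-normal baseline rate (ln-mean
1, ln-sd 1), multiplies the rates of each group's disjoint 10% marker-gene
block by (1 + effect) in that group's cells, and draws Poisson counts.

Study conditions used by the tests and the acceptance script: flat
recovery at n = 400, four blocks of 100, p_in = 0.2, p_out = 0.02 (the
within/between ratio of 10 with a kNN-like mean degree ≈ 26); nested
recovery at n = 400, 2×2 blocks of 100, p_in = 0.2, p_out = 0.002 — at
B_0 = 4 the intermediate level is worth only a few nats, and this macro
separation is where the true three-level hierarchy has strictly lower Σ
than micro+root, i.e. where the hierarchy is actually identifiable;
null graphs at n = 500, mean degree 15; expression experiments at 300–400
cells, 400–500 genes, effect 5.

What the generators do **not** emulate: dropout curves, library-size
gradients, batch effects, doublets, or any platform-specific noise.
Passing tests therefore demonstrate correctness of the inference machinery
and its statistical contracts under the stated generative conditions, not
performance on real tissue data.

## Numerical choices and edge cases

* All description lengths in nats; `lgamma`-based log-combinatorics
  throughout, no factorial overflow.
* Greedy acceptance threshold 1e−10 nats (guards float noise); convergence
  when improvement per sweep stays below 1e−8 nats for `patience` sweeps.
* Empty blocks are compacted immediately (labels never have gaps); the
  label of a compacted partition is the ascending-original-label order.
* kNN distance ties break by ascending cell index (stable argsort);
  duplicate points are allowed.
* Edge shuffling performs 10·|E| successful double-edge swaps, rejecting
  self-loops and duplicates, so per-node degrees are conserved exactly; a
  configuration-model endpoint re-pairing is available as `mode="relabel"`.
* White noise: per-gene moments exclude zeros; genes with fewer than two
  non-zero values get σ_g = 0; the sample (n−1) standard deviation is used.
* `affinity_matrix` orders columns by sorted label with "Unknown" last;
  the order is recorded on the result.

## Known limitations

* The dense block matrix in the kernel is O(B_cap²) memory; graphs beyond
  a few thousand cells start from a random 2048-block partition rather
  than singletons.
* Merge/split proposals at finite β use simple documented proposal
  distributions (uniform pair merges, fair-coin bisection splits); they
  satisfy detailed balance within that proposal family but mix slowly, so
  equilibrium sampling of the posterior is out of scope — the MCMC is used
  as a minimiser with stochastic diversification.
* Consensus is single-mode: ensembles whose restarts fall into genuinely
  different modes are averaged after alignment to the best model rather
  than decomposed into partition modes.
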