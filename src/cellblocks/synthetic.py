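"""Synthetic graphs and expression matrices with known planted structure.

These generators define the conditions under which the clustering stack is
exercised offline: Bernoulli block-model graphs (flat or two-level nested,
optionally degree-heterogeneous) and grouped count matrices with
marker-gene mean shifts.  They emulate the *structure* of single-cell
data, not its full noise model (no dropout curves, no library-size
gradients); see docs/methods.md for what that implies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import CellGraph, ExpressionMatrix
from .sbm import NestedPartition

__all__ = ["PlantedSpec", "generate_sbm_graph", "generate_expression"]


@dataclass
class PlantedSpec:
    """Planted block structure.

    ``block_sizes`` is either a flat list of group sizes or a nested list
    (one inner list of micro-block sizes per macro block).  ``p_in`` is the
    within-(micro-)block edge probability, ``p_out`` the probability across
    macro blocks; in the nested case, pairs of micro blocks sharing a macro
    block connect at the geometric mean sqrt(p_in * p_out).  ``degree_skew``
    s >= 0 adds Pareto degree propensities theta = (1-U)^(-s) (s = 0 means
    homogeneous).
    """

    n_cells: int
    block_sizes: list
    p_in: float
    p_out: float
    degree_skew: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if self.degree_skew < 0:
            raise ValueError("degree_skew must be >= 0")
        if self._total() != self.n_cells:
            raise ValueError("block sizes must sum to n_cells")

    @property
    def nested(self) -> bool:
        return bool(self.block_sizes) and isinstance(self.block_sizes[0], (list, tuple))

    def _total(self) -> int:
        if self.nested:
            return int(sum(sum(m) for m in self.block_sizes))
        return int(sum(self.block_sizes))


def generate_sbm_graph(spec: PlantedSpec):
    """Sample a Bernoulli block-model graph.

    Returns ``(graph, truth)``: for a flat spec, ``truth`` is the planted
    assignment array; for a nested spec it is a :class:`NestedPartition`
    with the micro level first and the macro grouping above it.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.nested:
        micro_sizes = [s for macro in spec.block_sizes for s in macro]
        micro_to_macro = np.array(
            [mi for mi, macro in enumerate(spec.block_sizes) for _ in macro],
            dtype=np.int64,
        )
    else:
        micro_sizes = list(spec.block_sizes)
        micro_to_macro = np.arange(len(micro_sizes), dtype=np.int64)
    micro = np.repeat(np.arange(len(micro_sizes)), micro_sizes).astype(np.int64)
    macro = micro_to_macro[micro]
    n = spec.n_cells
    p_mid = float(np.sqrt(spec.p_in * spec.p_out))

    theta = np.ones(n)
    if spec.degree_skew > 0:
        theta = (1.0 - rng.random(n)) ** (-spec.degree_skew)
        theta /= theta.mean()

    prob = np.where(
        micro[:, None] == micro[None, :],
        spec.p_in,
        np.where(macro[:, None] == macro[None, :], p_mid, spec.p_out),
    )
    prob = np.minimum(prob * theta[:, None] * theta[None, :], 1.0)
    exp_degree = (prob.sum() - np.trace(prob)) / n
    if exp_degree < 1:
        warnings.warn(f"expected mean degree {exp_degree:.2f} < 1")
    draw = rng.random((n, n))
    iu = np.triu_indices(n, k=1)
    hit = draw[iu] < prob[iu]
    edges = np.column_stack((iu[0][hit], iu[1][hit])).astype(np.int64)
    g = CellGraph(n, edges)
    if spec.nested:
        levels = [micro, micro_to_macro]
        if len(spec.block_sizes) > 1:
            levels.append(np.zeros(len(spec.block_sizes), dtype=np.int64))
        return g, NestedPartition(levels)
    return g, micro


def generate_expression(
    groups, n_genes: int, effect: float, seed: int = 0
) -> ExpressionMatrix:
    """Grouped count matrix with marker-gene mean shifts.

    Baseline per-gene rates are log-normal (ln-mean 1, ln-sd 1); each group
    owns a disjoint block of 10% of the genes whose rate is multiplied by
    (1 + effect) in that group's cells.  Counts are Poisson draws, so the
    ``raw`` layer is returned.  ``effect = 0`` leaves no recoverable group
    structure.
    """
    if effect < 0:
        raise ValueError("effect must be >= 0")
    groups = np.asarray(groups, dtype=np.int64)
    rng = np.random.default_rng(seed)
    n_cells = groups.size
    n_groups = int(groups.max()) + 1
    base = rng.lognormal(mean=1.0, sigma=1.0, size=n_genes)
    marker_frac = 0.10
    per_group = max(1, int(marker_frac * n_genes))
    rates = np.tile(base, (n_cells, 1))
    for k in range(n_groups):
        lo = (k * per_group) % n_genes
        hi = min(lo + per_group, n_genes)
        rates[groups == k, lo:hi] *= 1.0 + effect
    counts = rng.poisson(rates).astype(float)
    return ExpressionMatrix(
        counts,
        [f"cell{i}" for i in range(n_cells)],
        [f"gene{j}" for j in range(n_genes)],
        layer="raw",
    )
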