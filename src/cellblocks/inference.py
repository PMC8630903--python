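"""Description-length minimisation by MCMC with multiple restarts.

Each restart runs an agglomerative phase (greedy merges from singletons), a
stochastic diversification phase (single-node Metropolis-Hastings sweeps at
inverse temperature ``beta``) and a greedy refinement phase, all on the
flat objective; the hierarchy is then grown level by level on the block
multigraph and polished with exact nested-delta sweeps.  Restart i uses
seed ``base_seed + i`` (the seed ladder), so ensembles are reproducible and
independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf, isinf, log

import numpy as np

from . import _kernel as K
from ._util import get_logq_table
from .preprocess import CellGraph
from .sbm import (
    NestedPartition,
    NestedState,
    _aggregate,
    _compact,
    _level0_matrix,
    description_length,
    flat_description_length,
    ppbm_objective,
)

__all__ = ["FitConfig", "mcmc_sweep", "minimize_nested", "minimize_ppbm", "PpbmFit"]

_MAX_LEVELS = 30
_INIT_BLOCK_CAP = 2048


@dataclass
class FitConfig:
    """Ensemble fitting parameters.

    ``beta`` is the inverse temperature of the stochastic phase: 1 mixes the
    restarts (sampling), ``inf`` makes every phase greedy.
    """

    n_init: int = 100
    max_sweeps: int = 200
    patience: int = 10
    beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


# ---------------------------------------------------------------------------
# Kernel plumbing
# ---------------------------------------------------------------------------


def _graph_csr(g: CellGraph):
    n = g.n_nodes
    deg = g.degrees()
    indptr = np.zeros(n + 1, dtype=np.int64)
    indptr[1:] = np.cumsum(deg)
    fill = indptr[:-1].copy()
    indices = np.empty(int(deg.sum()), dtype=np.int64)
    for u, v in g.edges:
        indices[fill[u]] = v
        fill[u] += 1
        indices[fill[v]] = u
        fill[v] += 1
    weights = np.ones(indices.size, dtype=np.int64)
    selfw = np.zeros(n, dtype=np.int64)
    return indptr, indices, weights, selfw, deg.astype(np.int64)


def _multigraph_csr(e_mat: np.ndarray):
    """CSR view of a block multigraph: off-diagonal weights plus separate
    self-loop weights (the diagonal, already twice the internal count)."""
    n = e_mat.shape[0]
    off = e_mat.copy()
    np.fill_diagonal(off, 0)
    nnz = (off > 0).sum(axis=1)
    indptr = np.zeros(n + 1, dtype=np.int64)
    indptr[1:] = np.cumsum(nnz)
    indices = np.empty(int(nnz.sum()), dtype=np.int64)
    weights = np.empty(int(nnz.sum()), dtype=np.int64)
    pos = 0
    for i in range(n):
        cols = np.flatnonzero(off[i])
        indices[pos : pos + cols.size] = cols
        weights[pos : pos + cols.size] = off[i, cols]
        pos += cols.size
    selfw = e_mat.diagonal().astype(np.int64).copy()
    deg = e_mat.sum(axis=1).astype(np.int64)
    return indptr, indices, weights, selfw, deg


def _init_summaries(mode, b, indptr, indices, weights, selfw, deg, kmax):
    n = b.size
    cap = n
    B = int(b.max()) + 1
    e = np.zeros((cap + 1, cap + 1), dtype=np.int64)
    for i in range(n):
        r = b[i]
        for p in range(indptr[i], indptr[i + 1]):
            e[r, b[indices[p]]] += weights[p]
        e[r, r] += selfw[i]
    er = e[: cap + 1].sum(axis=1).astype(np.int64)
    nr = np.zeros(cap + 1, dtype=np.int64)
    np.add.at(nr, b, 1)
    eta = np.zeros((cap + 1, kmax + 1), dtype=np.int64)
    if mode != K.MODE_MS:
        np.add.at(eta, (b, deg), 1)
    return B, e, er, nr, eta


def _kernel_fit(mode, indptr, indices, weights, selfw, deg, seed, cfg, b_init=None):
    """One restart: agglomerative ladder (forced merges halving B, greedy
    refinement and best-sigma bookkeeping at every rung), then a final
    polish from the best rung with optional stochastic sweeps."""
    n = deg.size
    E = int(deg.sum()) // 2
    kmax = int(deg.max()) if n else 0
    logq = np.ascontiguousarray(get_logq_table(max(int(deg.sum()), 1), n))
    if b_init is None:
        if n <= _INIT_BLOCK_CAP:
            b = np.arange(n, dtype=np.int64)
        else:
            rng = np.random.default_rng(seed)
            b = _compact(rng.integers(0, _INIT_BLOCK_CAP, n))
    else:
        b = _compact(b_init)
    lfact_k_sum = (
        float(np.sum([K._lf(int(k)) for k in deg])) if mode != K.MODE_MS else 0.0
    )
    beta = cfg.beta if not isinf(cfg.beta) else 0.0
    n_mh = min(10, cfg.max_sweeps)

    def summaries(bb):
        return _init_summaries(mode, bb, indptr, indices, weights, selfw, deg, kmax)

    best_b = b.copy()
    best_sigma = np.inf
    step = 0
    target = int(b.max()) + 1
    while True:
        B, e, er, nr, eta = summaries(b)
        B, sigma, _ = K.fit_kernel(
            mode, (seed + 31 * step + 1) % (2**31), 0.0, 0,
            min(cfg.max_sweeps, 20), min(cfg.patience, 3),
            n, E, indptr, indices, weights, selfw, deg, b,
            e, er, nr, eta, logq, lfact_k_sum, False, False,
        )
        b = _compact(b)
        if sigma < best_sigma - 1e-12:
            best_sigma = float(sigma)
            best_b = b.copy()
        if target <= 1:
            break
        # the rung targets halve on a fixed schedule so the ladder always
        # terminates even if refinement regrows blocks
        target = max(1, target // 2)
        Bc = int(b.max()) + 1
        if Bc > target:
            B, e, er, nr, eta = summaries(b)
            K.forced_merge(
                mode, (seed + 31 * step + 2) % (2**31), target,
                n, E, b, Bc, e, er, nr, eta, logq, 5,
            )
            b = _compact(b)
        step += 1

    b = best_b.copy()
    B, e, er, nr, eta = summaries(b)
    B, sigma, _ = K.fit_kernel(
        mode, seed % (2**31), beta, n_mh, cfg.max_sweeps, cfg.patience,
        n, E, indptr, indices, weights, selfw, deg, b,
        e, er, nr, eta, logq, lfact_k_sum, True, True,
    )
    b = _compact(b)
    if sigma <= best_sigma:
        return b, float(sigma)
    return best_b, float(best_sigma)


# ---------------------------------------------------------------------------
# Python-level sweeps on the exact nested state
# ---------------------------------------------------------------------------


def mcmc_sweep(
    state: NestedState,
    level: int,
    rng: np.random.Generator,
    beta: float = inf,
    p_merge: float = 0.1,
    p_split: float = 0.05,
) -> tuple[NestedState, int, float]:
    """One sweep of merge-split multiflip proposals at one hierarchy level.

    Proposals are single-node moves (uniform over the B+1 labels at finite
    beta, best-of-candidates when greedy), block merges and random-bisection
    block splits, accepted by Metropolis-Hastings on exp(-beta * dSigma)
    with the documented proposal-probability ratios.  At ``beta = inf``
    only strictly improving proposals are applied, so sigma is
    non-increasing within the sweep.
    """
    accepted = 0
    total = 0.0
    n = state.partition.levels[level].size
    greedy = isinf(beta)
    for i in rng.permutation(n):
        B = state.block_counts[level]
        u = rng.random()
        if u < p_merge and B > 1:
            d = _try_merge(state, level, rng, beta, p_merge, p_split, greedy)
        elif u < p_merge + p_split and B < n:
            d = _try_split(state, level, rng, beta, p_merge, p_split, greedy)
        else:
            d = _try_move(state, level, int(i), rng, beta, greedy)
        if d is not None:
            accepted += 1
            total += d
    return state, accepted, total


def _try_move(state, level, node, rng, beta, greedy):
    b = state.partition.levels[level]
    B = state.block_counts[level]
    r = int(b[node])
    if greedy:
        cands = set()
        w, _, _ = state._node_block_weights(level, node)
        cands.update(w.keys())
        cands.add(int(rng.integers(0, B)))
        # block creation goes through the exact-but-slow structural path;
        # propose it sparsely
        if rng.random() < 0.05:
            cands.add(B)
        cands.discard(r)
        best, best_s = -1e-12, None
        for s in cands:
            d = state.delta_dl_move(level, node, s)
            if d < best:
                best, best_s = d, s
        if best_s is None:
            return None
        state.apply_move(level, node, best_s)
        return best
    s = int(rng.integers(0, B + 1))
    if s == r:
        return None
    d = state.delta_dl_move(level, node, s)
    m_r = int(state._m[level][r])
    Bn = B + (1 if s == B else 0) - (1 if m_r == 1 else 0)
    log_acc = -beta * d + log((B + 1.0) / (Bn + 1.0))
    if log_acc >= 0 or log(rng.random()) < log_acc:
        state.apply_move(level, node, s)
        return d
    return None


def _relabel_block(state, level, r, s):
    """Sigma difference of merging block r into s at ``level`` (computed on
    a copy), plus the merged partition's levels."""
    from .sbm import _apply_to_levels

    levels = [x.copy() for x in state.partition.levels]
    nodes = np.flatnonzero(levels[level] == r)
    new_levels = levels
    # block r only empties (triggering label compaction) on the last move,
    # after which the target label is no longer needed
    for nd in nodes:
        new_levels = _apply_to_levels(new_levels, level, int(nd), int(s))
    return new_levels


def _try_merge(state, level, rng, beta, p_merge, p_split, greedy):
    B = state.block_counts[level]
    r, s = rng.choice(B, size=2, replace=False)
    new_levels = _relabel_block(state, level, int(r), int(s))
    new_sigma = description_length(
        state.graph, NestedPartition(new_levels), state.degree_corrected
    ).total
    d = new_sigma - state.sigma
    if greedy:
        ok = d < -1e-12
    else:
        n_merged = int(state._m[level][r] + state._m[level][s])
        log_fwd = log(p_merge) - log(B * (B - 1))
        Bn = B - 1
        log_rev = log(p_split) - log(Bn) + (1 - n_merged) * log(2.0)
        log_acc = -beta * d + log_rev - log_fwd
        ok = log_acc >= 0 or log(rng.random()) < log_acc
    if ok:
        state.partition = NestedPartition(new_levels)
        state._rebuild()
        return d
    return None


def _try_split(state, level, rng, beta, p_merge, p_split, greedy):
    from .sbm import _apply_to_levels

    B = state.block_counts[level]
    r = int(rng.integers(0, B))
    members = np.flatnonzero(state.partition.levels[level] == r)
    if members.size < 2:
        return None
    coin = rng.integers(0, 2, size=members.size)
    if coin.sum() == 0 or coin.sum() == members.size:
        return None
    new_levels = [x.copy() for x in state.partition.levels]
    moved = members[coin == 1]
    target = B
    for nd in moved:
        new_levels = _apply_to_levels(new_levels, level, int(nd), int(target))
        target = int(new_levels[level][moved[0]])  # stick to the fresh block
    new_sigma = description_length(
        state.graph, NestedPartition(new_levels), state.degree_corrected
    ).total
    d = new_sigma - state.sigma
    if greedy:
        ok = d < -1e-12
    else:
        log_fwd = log(p_split) - log(B) + (1 - members.size) * log(2.0)
        Bn = B + 1
        log_rev = log(p_merge) + log(2.0) - log(Bn * (Bn - 1))
        log_acc = -beta * d + log_rev - log_fwd
        ok = log_acc >= 0 or log(rng.random()) < log_acc
    if ok:
        state.partition = NestedPartition(new_levels)
        state._rebuild()
        return d
    return None


def _refine(state: NestedState, rng: np.random.Generator, patience: int,
            max_rounds: int = 20) -> NestedState:
    """Alternate greedy node-move sweeps across all levels until no round
    improves (merge/split proposals are left to the flat kernel phases;
    here only the exact nested deltas are cheap enough per proposal)."""
    stall = 0
    rounds = 0
    while stall < min(patience, 3) and rounds < max_rounds:
        before = state.sigma
        for level in range(state.n_levels):
            n = state.partition.levels[level].size
            if n <= 1:
                continue
            for i in rng.permutation(n):
                _try_move(state, level, int(i), rng, inf, True)
        rounds += 1
        if before - state.sigma > 1e-8:
            stall = 0
        else:
            stall += 1
    return state


# ---------------------------------------------------------------------------
# Ensemble minimisers
# ---------------------------------------------------------------------------


def _fit_one_nested(g: CellGraph, cfg: FitConfig, seed: int,
                    refine: bool) -> NestedState:
    indptr, indices, weights, selfw, deg = _graph_csr(g)
    b0, _ = _kernel_fit(K.MODE_DC, indptr, indices, weights, selfw, deg, seed, cfg)
    levels = [b0]
    e_mat = _level0_matrix(g, b0, int(b0.max()) + 1)
    sub = 1
    while int(levels[-1].max()) + 1 > 1 and len(levels) < _MAX_LEVELS:
        B_prev = int(levels[-1].max()) + 1
        mi, mx, mw, msw, mdeg = _multigraph_csr(e_mat)
        bl, _ = _kernel_fit(
            K.MODE_MS, mi, mx, mw, msw, mdeg, seed + 7919 * sub, cfg
        )
        B_new = int(bl.max()) + 1
        if B_new >= B_prev:
            bl = np.zeros(B_prev, dtype=np.int64)
            B_new = 1
        levels.append(bl)
        if B_new == 1:
            break
        e_mat = _aggregate(e_mat, bl, B_new)
        sub += 1
    state = NestedState(g, NestedPartition(levels))
    if refine:
        state = _refine(state, np.random.default_rng(seed), cfg.patience)
    return state


def minimize_nested(
    g: CellGraph, cfg: FitConfig | None = None, refine: bool = True
) -> list[NestedState]:
    """Fit ``cfg.n_init`` nested models; returns states sorted by sigma.

    Restart i uses seed ``cfg.seed + i``; runs are independent, so the
    result does not depend on execution order.
    """
    if g.n_nodes == 0 or g.n_edges == 0:
        raise ValueError("cannot fit an empty graph")
    cfg = cfg or FitConfig()
    states = []
    for i in range(cfg.n_init):
        st = _fit_one_nested(g, cfg, (cfg.seed + i) % (2**31), refine)
        st.seed = (cfg.seed + i) % (2**31)
        states.append(st)
    states.sort(key=lambda s: s.sigma)
    return states


def minimize_flat(g: CellGraph, cfg: FitConfig | None = None) -> list[NestedState]:
    """Flat degree-corrected SBM fits (hierarchy fixed to one root level)."""
    if g.n_nodes == 0 or g.n_edges == 0:
        raise ValueError("cannot fit an empty graph")
    cfg = cfg or FitConfig()
    indptr, indices, weights, selfw, deg = _graph_csr(g)
    states = []
    for i in range(cfg.n_init):
        seed = (cfg.seed + i) % (2**31)
        b, _ = _kernel_fit(K.MODE_DC, indptr, indices, weights, selfw, deg, seed, cfg)
        st = NestedState(g, b)
        st.seed = seed
        states.append(st)
    states.sort(key=lambda s: s.sigma)
    return states


@dataclass
class PpbmFit:
    """A flat planted-partition fit: assignment, objective (nats), seed."""

    b: np.ndarray
    objective: float
    seed: int


def minimize_ppbm(g: CellGraph, cfg: FitConfig | None = None) -> list[PpbmFit]:
    """Fit ``cfg.n_init`` planted-partition models; sorted by objective."""
    if g.n_nodes == 0 or g.n_edges == 0:
        raise ValueError("cannot fit an empty graph")
    cfg = cfg or FitConfig()
    indptr, indices, weights, selfw, deg = _graph_csr(g)
    fits = []
    for i in range(cfg.n_init):
        seed = (cfg.seed + i) % (2**31)
        b, _ = _kernel_fit(K.MODE_PP, indptr, indices, weights, selfw, deg, seed, cfg)
        fits.append(PpbmFit(b, ppbm_objective(g, b), seed))
    fits.sort(key=lambda f: f.objective)
    return fits
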