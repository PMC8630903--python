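"""Microcanonical (nested) degree-corrected SBM description length.

The description length of a graph A under a nested partition b with
parameters theta = (block edge-count matrices e, degree sequence k) is

    Sigma = -ln P(A | theta, b) - ln P(theta, b)        [nats]

with the microcanonical ingredients fixed as follows and frozen by the
enumeration tests:

* level-0 likelihood (degree-corrected): the configuration-count formula
  -ln P(A|k,e,b) = -[ sum_{r<s} ln e_rs! + sum_r ln e_rr!!
                      + sum_i ln k_i! - sum_r ln e_r! ],
  where e_rr stores twice the internal edge count and e_r = sum_s e_rs;
* degree prior (uniform hyperprior): per block,
  -ln P(k_r) = ln n_r! - sum_k ln eta_rk! + ln q(e_r, n_r),
  with eta_rk the number of degree-k nodes in block r and q(m, n) the
  number of partitions of m into at most n parts;
* partition prior per level:
  -ln P(b_l) = ln n! - sum_r ln n_r! + ln C(n-1, B-1) + ln n;
* each upper level l >= 1 describes the multigraph e_{l-1} with a
  non-degree-corrected multigraph SBM:
  U(l) = sum_{R<S} ln ((m_R m_S, e_RS)) + sum_R ln ((m_R(m_R+1)/2, e_RR/2)),
  where ((n, m)) is the multiset coefficient and m_R counts the level-(l-1)
  blocks inside block R.  The root's own 1x1 matrix (the total edge count)
  is a constant of the data and carries no term.

The planted-partition objective (PPBM) constrains the flat model to one
within-block and one between-block density; see :func:`ppbm_objective`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import inf, log
from pathlib import Path

import numpy as np

from ._util import get_logq_table, lbinom, ldfact_even, lfact, lmultiset, log_q
from .preprocess import CellGraph

__all__ = [
    "NestedPartition",
    "BlockGraph",
    "DLBreakdown",
    "NestedState",
    "description_length",
    "flat_description_length",
    "delta_dl_move",
    "ppbm_objective",
    "project_partition",
]


def _compact(b: np.ndarray) -> np.ndarray:
    """Relabel blocks to 0..B-1 (ascending original label order)."""
    _, inv = np.unique(np.asarray(b, dtype=np.int64), return_inverse=True)
    return inv.astype(np.int64)


@dataclass
class NestedPartition:
    """Per-level block assignments: level 0 maps cells to blocks, level
    l > 0 maps level-(l-1) blocks to blocks; the top level has one block."""

    levels: list[np.ndarray]

    def __post_init__(self) -> None:
        lv = [np.asarray(x, dtype=np.int64) for x in self.levels]
        if not lv:
            raise ValueError("a partition needs at least one level")
        prev_b = None
        for i, b in enumerate(lv):
            if b.size == 0:
                raise ValueError(f"level {i} is empty")
            bmax = int(b.max())
            if int(b.min()) < 0 or len(np.unique(b)) != bmax + 1:
                raise ValueError(f"level {i} is not a surjection onto 0..B-1")
            if prev_b is not None and b.size != prev_b:
                raise ValueError(
                    f"level {i} maps {b.size} blocks but level {i-1} has {prev_b}"
                )
            if prev_b is not None and bmax + 1 > prev_b:
                raise ValueError("block counts must be non-increasing")
            prev_b = bmax + 1
        if prev_b != 1:
            raise ValueError("top level must have exactly one block")
        self.levels = lv

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def block_counts(self) -> list[int]:
        return [int(b.max()) + 1 for b in self.levels]

    def project(self, level: int) -> np.ndarray:
        """Cell-level partition induced by composing levels 0..level."""
        if not 0 <= level < self.n_levels:
            raise ValueError(f"level {level} out of range 0..{self.n_levels - 1}")
        acc = self.levels[0].copy()
        for l in range(1, level + 1):
            acc = self.levels[l][acc]
        return acc

    @classmethod
    def from_flat(cls, b: np.ndarray) -> "NestedPartition":
        b = _compact(b)
        levels = [b]
        if int(b.max()) + 1 > 1:
            levels.append(np.zeros(int(b.max()) + 1, dtype=np.int64))
        return cls(levels)

    def copy(self) -> "NestedPartition":
        return NestedPartition([b.copy() for b in self.levels])

    def to_json(self) -> str:
        return json.dumps(
            {
                "levels": [b.tolist() for b in self.levels],
                "block_counts": self.block_counts,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NestedPartition":
        data = json.loads(text)
        return cls([np.asarray(b, dtype=np.int64) for b in data["levels"]])

    def to_tsv(self, path: str | Path, cell_ids: list[str] | None = None) -> None:
        """Per-cell TSV, one column per hierarchy level (projected labels)."""
        n = self.levels[0].size
        cols = {f"level_{l}": self.project(l) for l in range(self.n_levels)}
        import pandas as pd

        idx = cell_ids if cell_ids is not None else [str(i) for i in range(n)]
        pd.DataFrame(cols, index=idx).to_csv(path, sep="\t", index_label="cell")


@dataclass
class BlockGraph:
    """Symmetric matrix of edge counts between blocks; e[r, r] stores twice
    the internal edge count, so e.sum() == 2E."""

    B: int
    e: np.ndarray

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=np.int64)
        if self.e.shape != (self.B, self.B):
            raise ValueError("e must be B x B")
        if (self.e != self.e.T).any() or (self.e < 0).any():
            raise ValueError("e must be symmetric and non-negative")


@dataclass
class DLBreakdown:
    """Description length in nats, with its additive terms.

    ``per_level[l-1]`` holds the upper-level edge-matrix term U(l) for
    l = 1..L; ``total`` is the sum of all terms.
    """

    edge_likelihood: float
    degree_prior: float
    partition_prior: float
    per_level: list[float]

    @property
    def total(self) -> float:
        return (
            self.edge_likelihood
            + self.degree_prior
            + self.partition_prior
            + sum(self.per_level)
        )


# ---------------------------------------------------------------------------
# Term computations
# ---------------------------------------------------------------------------


def _level0_matrix(g: CellGraph, b: np.ndarray, B: int) -> np.ndarray:
    e = np.zeros((B, B), dtype=np.int64)
    for u, v in g.edges:
        r, s = b[u], b[v]
        if r == s:
            e[r, r] += 2
        else:
            e[r, s] += 1
            e[s, r] += 1
    return e


def _aggregate(e_prev: np.ndarray, b: np.ndarray, B: int) -> np.ndarray:
    z = np.zeros((e_prev.shape[0], B), dtype=np.int64)
    z[np.arange(e_prev.shape[0]), b] = 1
    return z.T @ e_prev @ z


def _sizes(b: np.ndarray, B: int) -> np.ndarray:
    return np.bincount(b, minlength=B).astype(np.int64)


def _t_data_dc(e: np.ndarray, lfact_k_sum: float) -> float:
    B = e.shape[0]
    acc = lfact_k_sum
    for r in range(B):
        acc += ldfact_even(int(e[r, r]))
        acc -= lfact(int(e[r].sum()))
        for s in range(r + 1, B):
            acc += lfact(int(e[r, s]))
    return -acc


def _t_data_nondc(e: np.ndarray, m: np.ndarray) -> float:
    B = e.shape[0]
    acc = 0.0
    for r in range(B):
        acc += lbinom(int(m[r]) * (int(m[r]) - 1) // 2, int(e[r, r]) // 2)
        for s in range(r + 1, B):
            acc += lbinom(int(m[r]) * int(m[s]), int(e[r, s]))
    return acc


def _t_deg(
    e: np.ndarray, m: np.ndarray, eta: list[dict[int, int]], logq: np.ndarray
) -> float:
    acc = 0.0
    for r in range(e.shape[0]):
        acc += lfact(int(m[r])) + log_q(int(e[r].sum()), int(m[r]), logq)
        for cnt in eta[r].values():
            acc -= lfact(cnt)
    return acc


def _t_part(m: np.ndarray) -> float:
    n = int(m.sum())
    B = m.size
    return (
        lfact(n)
        - sum(lfact(int(x)) for x in m)
        + lbinom(n - 1, B - 1)
        + log(n)
    )


def _u_term(e: np.ndarray, m: np.ndarray) -> float:
    B = e.shape[0]
    acc = 0.0
    for r in range(B):
        acc += lmultiset(int(m[r]) * (int(m[r]) + 1) // 2, int(e[r, r]) // 2)
        for s in range(r + 1, B):
            acc += lmultiset(int(m[r]) * int(m[s]), int(e[r, s]))
    return acc


def _degree_hist(b: np.ndarray, B: int, degrees: np.ndarray) -> list[dict[int, int]]:
    eta: list[dict[int, int]] = [dict() for _ in range(B)]
    for i in range(b.size):
        d = eta[b[i]]
        k = int(degrees[i])
        d[k] = d.get(k, 0) + 1
    return eta


def description_length(
    g: CellGraph, b: NestedPartition | np.ndarray, degree_corrected: bool = True
) -> DLBreakdown:
    """Exact nested description length of ``g`` under partition ``b`` (nats).

    ``b`` may be a :class:`NestedPartition` or a flat assignment array (a
    root level is appended automatically).  The value is invariant under any
    permutation of block labels at any level.
    """
    if not isinstance(b, NestedPartition):
        b = NestedPartition.from_flat(np.asarray(b))
    if b.levels[0].size != g.n_nodes:
        raise ValueError(
            f"partition covers {b.levels[0].size} nodes, graph has {g.n_nodes}"
        )
    degrees = g.degrees()
    counts = b.block_counts
    L = b.n_levels - 1

    e_mats = [_level0_matrix(g, b.levels[0], counts[0])]
    for l in range(1, b.n_levels):
        e_mats.append(_aggregate(e_mats[-1], b.levels[l], counts[l]))
    m_list = [_sizes(b.levels[l], counts[l]) for l in range(b.n_levels)]

    lfact_k_sum = float(sum(lfact(int(k)) for k in degrees))
    if degree_corrected:
        edge_like = _t_data_dc(e_mats[0], lfact_k_sum)
        logq = get_logq_table(int(degrees.sum()), g.n_nodes)
        eta = _degree_hist(b.levels[0], counts[0], degrees)
        deg_prior = _t_deg(e_mats[0], m_list[0], eta, logq)
    else:
        edge_like = _t_data_nondc(e_mats[0], m_list[0])
        deg_prior = 0.0
    part_prior = sum(_t_part(m_list[l]) for l in range(b.n_levels))
    per_level = [_u_term(e_mats[l], m_list[l]) for l in range(1, L + 1)]
    return DLBreakdown(edge_like, deg_prior, part_prior, per_level)


def flat_description_length(
    g: CellGraph, b: np.ndarray, degree_corrected: bool = True
) -> float:
    """Sigma of the flat model: the partition plus a single root level."""
    return description_length(g, NestedPartition.from_flat(b), degree_corrected).total


def project_partition(b: NestedPartition, level: int) -> np.ndarray:
    """Cell-level partition obtained by composing levels 0..level."""
    return b.project(level)


def ppbm_objective(g: CellGraph, b: np.ndarray) -> float:
    """Description length under the planted-partition block model (nats).

    The PPBM constrains the degree-corrected SBM so that all between-block
    pairs share a single edge budget e_out, spread uniformly over the
    B(B-1)/2 pairs, and the within-block budget e_in is split over blocks
    with a uniform multiset prior.  At B = 1 the likelihood term coincides
    with the one-block degree-corrected SBM.
    """
    b = _compact(np.asarray(b))
    if b.size != g.n_nodes:
        raise ValueError("partition size does not match graph")
    B = int(b.max()) + 1
    degrees = g.degrees()
    E = g.n_edges
    e = _level0_matrix(g, b, B)
    m = _sizes(b, B)
    e_in = int(e.diagonal().sum()) // 2
    e_out = E - e_in

    like = float(sum(lfact(int(k)) for k in degrees)) + lfact(e_out)
    for r in range(B):
        like += ldfact_even(int(e[r, r]))
        like -= lfact(int(e[r].sum()))
    if B > 1:
        like -= e_out * log(B * (B - 1) / 2.0)
    t_like = -like

    logq = get_logq_table(int(degrees.sum()), g.n_nodes)
    eta = _degree_hist(b, B, degrees)
    t_deg = _t_deg(e, m, eta, logq)
    t_e = log(E + 1.0) + lmultiset(B, e_in)
    return t_like + t_deg + t_e + _t_part(m)


# ---------------------------------------------------------------------------
# Incremental state
# ---------------------------------------------------------------------------


class NestedState:
    """Graph + nested partition + cached block matrices and DL terms.

    Supports exact move deltas: the generic path recomputes only the terms
    touched by a move (rows of the affected block matrices, walking the
    change up the hierarchy); moves that create or empty a block fall back
    to an exact recompute on a copy, since those cascade structurally.
    """

    def __init__(
        self,
        graph: CellGraph,
        partition: NestedPartition | np.ndarray,
        degree_corrected: bool = True,
    ) -> None:
        if not isinstance(partition, NestedPartition):
            partition = NestedPartition.from_flat(np.asarray(partition))
        self.graph = graph
        self.degree_corrected = degree_corrected
        self.partition = partition.copy()
        self._adj = graph.adjacency_lists()
        self._degrees = graph.degrees()
        self._lfact_k_sum = float(sum(lfact(int(k)) for k in self._degrees))
        self._logq = get_logq_table(int(self._degrees.sum()), graph.n_nodes)
        self._rebuild()

    # -- cache construction -------------------------------------------------

    def _rebuild(self) -> None:
        part = self.partition
        counts = part.block_counts
        self._counts = counts
        self._e = [_level0_matrix(self.graph, part.levels[0], counts[0])]
        for l in range(1, part.n_levels):
            self._e.append(_aggregate(self._e[-1], part.levels[l], counts[l]))
        self._m = [_sizes(part.levels[l], counts[l]) for l in range(part.n_levels)]
        if self.degree_corrected:
            self._eta = _degree_hist(part.levels[0], counts[0], self._degrees)
            self._t_data = _t_data_dc(self._e[0], self._lfact_k_sum)
            self._t_deg = _t_deg(self._e[0], self._m[0], self._eta, self._logq)
        else:
            self._eta = None
            self._t_data = _t_data_nondc(self._e[0], self._m[0])
            self._t_deg = 0.0
        self._t_part = [_t_part(self._m[l]) for l in range(part.n_levels)]
        self._u = [
            _u_term(self._e[l], self._m[l]) for l in range(1, part.n_levels)
        ]

    # -- public surface -----------------------------------------------------

    @property
    def n_levels(self) -> int:
        return self.partition.n_levels

    @property
    def block_counts(self) -> list[int]:
        return list(self._counts)

    @property
    def block_graphs(self) -> list[BlockGraph]:
        return [BlockGraph(ee.shape[0], ee.copy()) for ee in self._e]

    @property
    def degrees(self) -> np.ndarray:
        return self._degrees.copy()

    @property
    def sigma(self) -> float:
        return self.breakdown.total

    @property
    def breakdown(self) -> DLBreakdown:
        return DLBreakdown(
            self._t_data, self._t_deg, float(sum(self._t_part)), list(self._u)
        )

    def copy(self) -> "NestedState":
        return NestedState(self.graph, self.partition, self.degree_corrected)

    def project(self, level: int) -> np.ndarray:
        return self.partition.project(level)

    # -- move machinery -----------------------------------------------------

    def _node_block_weights(self, level: int, node: int) -> tuple[dict, int, int]:
        """Edge weight from ``node`` to each block at ``level``, the node's
        self-loop weight and its (multigraph) degree."""
        b = self.partition.levels[level]
        w: dict[int, int] = {}
        if level == 0:
            for v in self._adj[node]:
                t = int(b[v])
                w[t] = w.get(t, 0) + 1
            return w, 0, int(self._degrees[node])
        row = self._e[level - 1][node]
        for x in np.flatnonzero(row):
            t = int(b[x])
            w[t] = w.get(t, 0) + int(row[x])
        u_self = int(row[node])
        r = int(b[node])
        if u_self:
            w[r] = w.get(r, 0) - u_self
            if w[r] == 0:
                del w[r]
        return w, u_self, int(row.sum())

    def delta_dl_move(self, level: int, node: int, target_block: int) -> float:
        """Sigma(after move) - Sigma(before); the state is not modified."""
        part = self.partition
        if not 0 <= level < part.n_levels:
            raise ValueError(f"level {level} out of range")
        b = part.levels[level]
        if not 0 <= node < b.size:
            raise ValueError(f"node {node} does not exist at level {level}")
        B = self._counts[level]
        if not 0 <= target_block <= B:
            raise ValueError(f"target block {target_block} out of range 0..{B}")
        r = int(b[node])
        s = int(target_block)
        if r == s:
            return 0.0
        if s == B or int(self._m[level][r]) == 1:
            return self._delta_slow(level, node, s)
        return self._delta_fast(level, node, r, s)

    def _delta_fast(self, level: int, node: int, r: int, s: int) -> float:
        w, u_self, kappa = self._node_block_weights(level, node)
        w_r = w.get(r, 0)
        w_s = w.get(s, 0)
        e = self._e[level]
        B = self._counts[level]
        delta = 0.0

        # ordered-entry updates to e[level]
        upd: dict[tuple[int, int], int] = {}

        def add(x: int, y: int, d: int) -> None:
            if d:
                upd[(x, y)] = upd.get((x, y), 0) + d
                if x != y:
                    upd[(y, x)] = upd.get((y, x), 0) + d

        for t, wt in w.items():
            if t not in (r, s):
                add(r, t, -wt)
                add(s, t, wt)
        add(r, r, -2 * w_r - u_self)
        add(s, s, 2 * w_s + u_self)
        if w_r - w_s:
            upd[(r, s)] = upd.get((r, s), 0) + (w_r - w_s)
            upd[(s, r)] = upd.get((s, r), 0) + (w_r - w_s)

        def newval(x: int, y: int) -> int:
            return int(e[x, y]) + upd.get((x, y), 0)

        m = self._m[level]
        mr, ms = int(m[r]), int(m[s])
        if level == 0 and self.degree_corrected:
            old = new = 0.0
            for t in range(B):
                if t in (r, s):
                    continue
                old += lfact(int(e[r, t])) + lfact(int(e[s, t]))
                new += lfact(newval(r, t)) + lfact(newval(s, t))
            old += lfact(int(e[r, s])) + ldfact_even(int(e[r, r]))
            old += ldfact_even(int(e[s, s]))
            new += lfact(newval(r, s)) + ldfact_even(newval(r, r))
            new += ldfact_even(newval(s, s))
            er, es = int(e[r].sum()), int(e[s].sum())
            old -= lfact(er) + lfact(es)
            new -= lfact(er - kappa) + lfact(es + kappa)
            delta += -(new - old)
            # degree hyperprior for blocks r and s
            kd = int(self._degrees[node])
            eta_r = self._eta[r].get(kd, 0)
            eta_s = self._eta[s].get(kd, 0)
            delta += (
                lfact(mr - 1)
                - lfact(mr)
                + lfact(eta_r)
                - lfact(eta_r - 1)
                + log_q(er - kappa, mr - 1, self._logq)
                - log_q(er, mr, self._logq)
            )
            delta += (
                lfact(ms + 1)
                - lfact(ms)
                + lfact(eta_s)
                - lfact(eta_s + 1)
                + log_q(es + kappa, ms + 1, self._logq)
                - log_q(es, ms, self._logq)
            )
        elif level == 0:
            old = new = 0.0
            for t in range(B):
                if t in (r, s):
                    continue
                mt = int(m[t])
                old += lbinom(mr * mt, int(e[r, t])) + lbinom(ms * mt, int(e[s, t]))
                new += lbinom((mr - 1) * mt, newval(r, t)) + lbinom(
                    (ms + 1) * mt, newval(s, t)
                )
            old += lbinom(mr * ms, int(e[r, s]))
            old += lbinom(mr * (mr - 1) // 2, int(e[r, r]) // 2)
            old += lbinom(ms * (ms - 1) // 2, int(e[s, s]) // 2)
            new += lbinom((mr - 1) * (ms + 1), newval(r, s))
            new += lbinom((mr - 1) * (mr - 2) // 2, newval(r, r) // 2)
            new += lbinom((ms + 1) * ms // 2, newval(s, s) // 2)
            delta += new - old
        else:
            old = new = 0.0
            for t in range(B):
                if t in (r, s):
                    continue
                mt = int(m[t])
                old += lmultiset(mr * mt, int(e[r, t]))
                old += lmultiset(ms * mt, int(e[s, t]))
                new += lmultiset((mr - 1) * mt, newval(r, t))
                new += lmultiset((ms + 1) * mt, newval(s, t))
            old += lmultiset(mr * ms, int(e[r, s]))
            old += lmultiset(mr * (mr + 1) // 2, int(e[r, r]) // 2)
            old += lmultiset(ms * (ms + 1) // 2, int(e[s, s]) // 2)
            new += lmultiset((mr - 1) * (ms + 1), newval(r, s))
            new += lmultiset((mr - 1) * mr // 2, newval(r, r) // 2)
            new += lmultiset((ms + 1) * (ms + 2) // 2, newval(s, s) // 2)
            delta += new - old

        # partition prior at this level (B unchanged on the fast path);
        # the -sum ln n_r! term gains ln(m_r) - ln(m_s + 1)
        delta += lfact(mr) - lfact(mr - 1) + lfact(ms) - lfact(ms + 1)

        # walk the edge-count changes up the hierarchy
        cur = upd
        for lu in range(level + 1, self.n_levels):
            bu = self.partition.levels[lu]
            nxt: dict[tuple[int, int], int] = {}
            for (x, y), d in cur.items():
                key = (int(bu[x]), int(bu[y]))
                nxt[key] = nxt.get(key, 0) + d
            nxt = {k: v for k, v in nxt.items() if v}
            if not nxt:
                break
            eu = self._e[lu]
            mu = self._m[lu]
            seen = set()
            for (x, y), d in nxt.items():
                key = (min(x, y), max(x, y))
                if key in seen:
                    continue
                seen.add(key)
                xx, yy = key
                old_v = int(eu[xx, yy])
                new_v = old_v + nxt.get((xx, yy), 0)
                if xx == yy:
                    arg = int(mu[xx]) * (int(mu[xx]) + 1) // 2
                    delta += lmultiset(arg, new_v // 2) - lmultiset(arg, old_v // 2)
                else:
                    arg = int(mu[xx]) * int(mu[yy])
                    delta += lmultiset(arg, new_v) - lmultiset(arg, old_v)
            cur = nxt
        return delta

    def _delta_slow(self, level: int, node: int, s: int) -> float:
        new_levels = _apply_to_levels(
            [b.copy() for b in self.partition.levels], level, node, s
        )
        new_sigma = description_length(
            self.graph, NestedPartition(new_levels), self.degree_corrected
        ).total
        return new_sigma - self.sigma

    def apply_move(self, level: int, node: int, target_block: int) -> None:
        """Move the node and refresh all caches (labels compacted)."""
        b = self.partition.levels[level]
        if int(b[node]) == int(target_block):
            return
        new_levels = _apply_to_levels(
            [x.copy() for x in self.partition.levels], level, node, int(target_block)
        )
        self.partition = NestedPartition(new_levels)
        self._rebuild()


def _apply_to_levels(
    levels: list[np.ndarray], level: int, node: int, s: int
) -> list[np.ndarray]:
    """Apply a node move to raw level arrays, handling block creation,
    emptied-block compaction (with upward cascade) and root maintenance."""
    b = levels[level]
    r = int(b[node])
    B = int(b.max()) + 1
    created = s == B
    b[node] = s
    if created:
        # the fresh block inherits the parent of the source block
        if level + 1 < len(levels):
            parent = int(levels[level + 1][r])
            levels[level + 1] = np.append(levels[level + 1], parent)
        else:
            # splitting the root: add a new root level above
            levels.append(np.zeros(B + 1, dtype=np.int64))
    if (b == r).sum() == 0:
        # source block emptied: compact labels and drop its upper-level node
        b[b > r] -= 1
        if level + 1 < len(levels):
            levels[level + 1] = np.delete(levels[level + 1], r)
            lv = level + 1
            while lv < len(levels):
                cur = levels[lv]
                # the label range of this level must match the node count of
                # the level above (len of the next assignment array)
                expected_b = (
                    levels[lv + 1].size if lv + 1 < len(levels) else int(cur.max()) + 1
                )
                present = set(np.unique(cur).tolist())
                missing = sorted(set(range(expected_b)) - present)
                if not missing:
                    break
                for gone in reversed(missing):
                    cur[cur > gone] -= 1
                    if lv + 1 < len(levels):
                        levels[lv + 1] = np.delete(levels[lv + 1], gone)
                levels[lv] = cur
                lv += 1
    # prune redundant trailing roots (chains of single-block levels)
    while len(levels) > 1 and int(levels[-2].max()) == 0:
        levels.pop()
    if int(levels[-1].max()) + 1 > 1:
        levels.append(np.zeros(int(levels[-1].max()) + 1, dtype=np.int64))
    return levels


def delta_dl_move(
    state: NestedState, level: int, node: int, target_block: int
) -> float:
    """Functional wrapper around :meth:`NestedState.delta_dl_move`."""
    return state.delta_dl_move(level, node, target_block)
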