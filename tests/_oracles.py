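"""Independent brute-force oracles used by the tests.

These deliberately avoid the incremental code paths they are used to
check: partitions are enumerated exhaustively and description lengths are
always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from cellblocks.sbm import flat_description_length


def set_partitions(n: int):
    """All partitions of {0..n-1} as lists of blocks (Bell(n) of them)."""
    if n == 0:
        yield []
        return
    for p in set_partitions(n - 1):
        for i in range(len(p)):
            yield p[:i] + [p[i] + [n - 1]] + p[i + 1 :]
        yield p + [[n - 1]]


def blocks_to_assignment(p, n: int) -> np.ndarray:
    b = np.empty(n, dtype=np.int64)
    for lbl, grp in enumerate(p):
        for x in grp:
            b[x] = lbl
    return b


def exhaustive_flat_minimum(g) -> tuple[float, np.ndarray]:
    """Minimum flat description length over all partitions, by enumeration."""
    best = np.inf
    best_b = None
    n = g.n_nodes
    for p in set_partitions(n):
        b = blocks_to_assignment(p, n)
        s = flat_description_length(g, b)
        if s < best:
            best = s
            best_b = b
    return best, best_b


def count_partitions_at_most(m: int, n: int) -> int:
    """q(m, n): partitions of integer m into at most n parts (brute force)."""
    if m == 0:
        return 1
    if n == 0:
        return 0

    def rec(remaining, max_part, parts_left):
        if remaining == 0:
            return 1
        if parts_left == 0:
            return 0
        total = 0
        for first in range(min(remaining, max_part), 0, -1):
            total += rec(remaining - first, first, parts_left - 1)
        return total

    return rec(m, m, n)


def random_graph(n: int, p: float, rng) -> np.ndarray:
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    return np.array(edges, dtype=np.int64).reshape(-1, 2)
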