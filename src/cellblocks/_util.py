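"""Log-combinatorics helpers shared by the description-length code.

Everything is computed in log space (natural log, i.e. nats) with
``math.lgamma`` so that factorials of edge counts never overflow.
"""

from __future__ import annotations

from math import lgamma, log

import numpy as np

__all__ = [
    "lfact",
    "lbinom",
    "lmultiset",
    "ldfact_even",
    "get_logq_table",
    "log_q",
]


def lfact(n: int) -> float:
    """ln n!"""
    return lgamma(n + 1.0)


def lbinom(n: int, k: int) -> float:
    """ln C(n, k) for 0 <= k <= n."""
    if k == 0 or k == n:
        return 0.0
    return lgamma(n + 1.0) - lgamma(k + 1.0) - lgamma(n - k + 1.0)


def lmultiset(n: int, m: int) -> float:
    """ln of the multiset coefficient ((n, m)) = C(n + m - 1, m).

    Number of ways to distribute m indistinguishable items over n slots.
    ((n, 0)) = 1 for every n (including n = 0, the empty distribution).
    """
    if m == 0:
        return 0.0
    return lbinom(n + m - 1, m)


def ldfact_even(n: int) -> float:
    """ln n!! for even n: n!! = 2^(n/2) (n/2)!"""
    half = n // 2
    return half * log(2.0) + lgamma(half + 1.0)


# ---------------------------------------------------------------------------
# Restricted partition numbers q(m, n) = number of partitions of the integer m
# into at most n parts.  Used by the uniform hyperprior on block degree
# sequences.  Built once per required size with the recurrence
# q(m, n) = q(m, n-1) + q(m-n, n), evaluated stably in log space.
# ---------------------------------------------------------------------------

_LOGQ_CACHE: dict[tuple[int, int], np.ndarray] = {}


def get_logq_table(m_max: int, n_max: int) -> np.ndarray:
    """Table T with T[m, n] = ln q(m, n), shape (m_max+1, n_max+1).

    T[m, n] = -inf where q(m, n) = 0 (m > 0, n = 0).
    """
    n_max = min(n_max, m_max) if m_max > 0 else n_max
    for (mm, nn), tab in _LOGQ_CACHE.items():
        if mm >= m_max and nn >= n_max:
            return tab[: m_max + 1, : n_max + 1]
    tab = np.full((m_max + 1, n_max + 1), -np.inf)
    tab[0, :] = 0.0
    for n in range(1, n_max + 1):
        col = tab[:, n - 1].copy()
        # col[m] += col[m - n] telescopes to a running log-sum along each
        # residue class mod n.
        for r in range(min(n, m_max + 1)):
            col[r::n] = np.logaddexp.accumulate(col[r::n])
        tab[:, n] = col
    if len(_LOGQ_CACHE) > 4:
        _LOGQ_CACHE.clear()
    _LOGQ_CACHE[(m_max, n_max)] = tab
    return tab


def log_q(m: int, n: int, table: np.ndarray | None = None) -> float:
    """ln q(m, n) for a single pair; q(m, n) = q(m, m) when n >= m."""
    if m == 0:
        return 0.0
    n_eff = min(n, m)
    if table is None or m >= table.shape[0] or n_eff >= table.shape[1]:
        table = get_logq_table(m, n_eff)
    return float(table[m, n_eff])
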