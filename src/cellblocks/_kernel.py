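"""Numba kernels for flat-level description-length minimisation.

Three objectives share one move/merge engine, selected by ``mode``:

* ``MODE_DC``   — degree-corrected SBM on the simple cell graph, plus the
  single-root closure terms (ln B and the multiset cost of the block
  matrix), i.e. exactly ``flat_description_length`` from :mod:`.sbm`;
* ``MODE_MS``   — non-degree-corrected multigraph SBM with multiset edge
  counts, used to group the block multigraph when building the hierarchy;
* ``MODE_PP``   — the planted-partition objective (``ppbm_objective``).

The kernels maintain the block edge-count matrix, row sums, block sizes and
per-block degree histograms incrementally; every delta is exact, so a
greedy sweep is monotone in the objective.  All randomness comes from
``np.random.seed`` called once per fit with the caller's seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

MODE_DC = 0
MODE_MS = 1
MODE_PP = 2

_EPS = 1e-10


@njit(cache=True)
def _lf(n):
    return math.lgamma(n + 1.0)


@njit(cache=True)
def _lbinom(n, k):
    if k <= 0 or k >= n:
        return 0.0
    return math.lgamma(n + 1.0) - math.lgamma(k + 1.0) - math.lgamma(n - k + 1.0)


@njit(cache=True)
def _lms(n, m):
    if m == 0:
        return 0.0
    return _lbinom(n + m - 1, m)


@njit(cache=True)
def _ldf(n):
    half = n // 2
    return half * math.log(2.0) + math.lgamma(half + 1.0)


@njit(cache=True)
def _logq(m, n, table):
    if m <= 0:
        return 0.0
    ne = n if n < m else m
    if ne >= table.shape[1]:
        ne = table.shape[1] - 1
    return table[m, ne]


@njit(cache=True)
def _closure(B, E):
    # root-level terms of the flat model: absent when B == 1
    if B < 2:
        return 0.0
    return math.log(B) + _lms(B * (B + 1) // 2, E)


@njit(cache=True)
def _part_prior(N, B, nr):
    acc = _lf(N) + _lbinom(N - 1, B - 1) + math.log(N)
    for r in range(B):
        acc -= _lf(nr[r])
    return acc


@njit(cache=True)
def full_objective(mode, N, E, indptr, indices, weights, selfw, deg, b, B,
                   e, er, nr, eta, lfact_k_sum, logq):
    """Objective recomputed from the maintained block summaries."""
    acc = _part_prior(N, B, nr)
    if mode == MODE_DC:
        like = lfact_k_sum
        for r in range(B):
            like += _ldf(e[r, r]) - _lf(er[r])
            for s in range(r + 1, B):
                like += _lf(e[r, s])
        acc -= like
        for r in range(B):
            acc += _lf(nr[r]) + _logq(er[r], nr[r], logq)
            for k in range(eta.shape[1]):
                if eta[r, k] > 1:
                    acc -= _lf(eta[r, k])
        acc += _closure(B, E)
    elif mode == MODE_MS:
        for r in range(B):
            acc += _lms(nr[r] * (nr[r] + 1) // 2, e[r, r] // 2)
            for s in range(r + 1, B):
                acc += _lms(nr[r] * nr[s], e[r, s])
        acc += _closure(B, E)
    else:  # MODE_PP
        e_in = 0
        for r in range(B):
            e_in += e[r, r]
        e_in //= 2
        e_out = E - e_in
        like = lfact_k_sum + _lf(e_out)
        for r in range(B):
            like += _ldf(e[r, r]) - _lf(er[r])
        if B > 1:
            like -= e_out * math.log(B * (B - 1) / 2.0)
        acc -= like
        for r in range(B):
            acc += _lf(nr[r]) + _logq(er[r], nr[r], logq)
            for k in range(eta.shape[1]):
                if eta[r, k] > 1:
                    acc -= _lf(eta[r, k])
        acc += math.log(E + 1.0) + _lms(B, e_in)
    return acc


@njit(cache=True)
def _gather(i, indptr, indices, weights, b, wsum, touched):
    """Edge weight from node i to each block; returns number touched and
    the node's total edge weight (excluding any self weight)."""
    nt = 0
    tot = 0
    for p in range(indptr[i], indptr[i + 1]):
        t = b[indices[p]]
        if wsum[t] == 0:
            touched[nt] = t
            nt += 1
        wsum[t] += weights[p]
        tot += weights[p]
    return nt, tot


@njit(cache=True)
def delta_move(mode, i, s_new, N, E, indptr, indices, weights, selfw, deg,
               b, B, e, er, nr, eta, logq, wsum, touched):
    """Exact objective change of moving node i to block s_new (== B means a
    fresh block).  Scratch arrays wsum/touched are zeroed on exit."""
    r = b[i]
    s = s_new
    if s == r:
        return 0.0
    nt, _ = _gather(i, indptr, indices, weights, b, wsum, touched)
    w_r = wsum[r]
    w_s = wsum[s] if s < B else 0
    u_self = selfw[i]
    kappa = deg[i]
    empties = nr[r] == 1
    creates = s == B
    Bn = B + (1 if creates else 0) - (1 if empties else 0)
    if empties and creates:
        for t in range(nt):
            wsum[touched[t]] = 0
        return 0.0
    d = 0.0

    if mode == MODE_DC:
        # likelihood: only entries with changed counts contribute
        old = 0.0
        new = 0.0
        for tt in range(nt):
            t = touched[tt]
            if t == r or t == s:
                continue
            wt = wsum[t]
            old += _lf(e[r, t]) + _lf(e[s, t] if s < B else 0)
            new += _lf(e[r, t] - wt) + _lf((e[s, t] if s < B else 0) + wt)
        e_rs = e[r, s] if s < B else 0
        e_ss = e[s, s] if s < B else 0
        old += _lf(e_rs) + _ldf(e[r, r]) + _ldf(e_ss)
        new += _lf(e_rs + w_r - w_s) + _ldf(e[r, r] - 2 * w_r) + _ldf(e_ss + 2 * w_s)
        er_s = er[s] if s < B else 0
        old -= _lf(er[r]) + _lf(er_s)
        new -= _lf(er[r] - kappa) + _lf(er_s + kappa)
        d -= new - old
        # degree hyperprior, blocks r and s
        kd = deg[i]
        eta_r = eta[r, kd]
        eta_s = eta[s, kd] if s < B else 0
        nr_s = nr[s] if s < B else 0
        d += (_lf(nr[r] - 1) - _lf(nr[r]) + _lf(eta_r) - _lf(eta_r - 1)
              + _logq(er[r] - kappa, nr[r] - 1, logq) - _logq(er[r], nr[r], logq))
        d += (_lf(nr_s + 1) - _lf(nr_s) + _lf(eta_s) - _lf(eta_s + 1)
              + _logq(er_s + kappa, nr_s + 1, logq) - _logq(er_s, nr_s, logq))
        if Bn != B:
            d += _closure(Bn, E) - _closure(B, E)
    elif mode == MODE_MS:
        # multiset likelihood: block sizes enter every pair term
        mr = nr[r]
        ms = nr[s] if s < B else 0
        old = 0.0
        new = 0.0
        for t in range(B):
            if t == r or t == s:
                continue
            wt = wsum[t]
            mt = nr[t]
            est = e[s, t] if s < B else 0
            old += _lms(mr * mt, e[r, t]) + _lms(ms * mt, est)
            new += _lms((mr - 1) * mt, e[r, t] - wt) + _lms((ms + 1) * mt, est + wt)
        e_rs = e[r, s] if s < B else 0
        e_ss = e[s, s] if s < B else 0
        old += _lms(mr * ms, e_rs)
        old += _lms(mr * (mr + 1) // 2, e[r, r] // 2)
        old += _lms(ms * (ms + 1) // 2, e_ss // 2)
        new += _lms((mr - 1) * (ms + 1), e_rs + w_r - w_s)
        new += _lms((mr - 1) * mr // 2, (e[r, r] - 2 * w_r - u_self) // 2)
        new += _lms((ms + 1) * (ms + 2) // 2, (e_ss + 2 * w_s + u_self) // 2)
        d += new - old
        if Bn != B:
            d += _closure(Bn, E) - _closure(B, E)
    else:  # MODE_PP
        e_in = 0
        for t in range(B):
            e_in += e[t, t]
        e_in //= 2
        e_out = E - e_in
        e_ss = e[s, s] if s < B else 0
        e_in_n = e_in - w_r + w_s
        e_out_n = E - e_in_n
        old = _ldf(e[r, r]) + _ldf(e_ss) + _lf(e_out)
        new = _ldf(e[r, r] - 2 * w_r) + _ldf(e_ss + 2 * w_s) + _lf(e_out_n)
        er_s = er[s] if s < B else 0
        old -= _lf(er[r]) + _lf(er_s)
        new -= _lf(er[r] - kappa) + _lf(er_s + kappa)
        if B > 1:
            old -= e_out * math.log(B * (B - 1) / 2.0)
        if Bn > 1:
            new -= e_out_n * math.log(Bn * (Bn - 1) / 2.0)
        d -= new - old
        kd = deg[i]
        eta_r = eta[r, kd]
        eta_s = eta[s, kd] if s < B else 0
        nr_s = nr[s] if s < B else 0
        d += (_lf(nr[r] - 1) - _lf(nr[r]) + _lf(eta_r) - _lf(eta_r - 1)
              + _logq(er[r] - kappa, nr[r] - 1, logq) - _logq(er[r], nr[r], logq))
        d += (_lf(nr_s + 1) - _lf(nr_s) + _lf(eta_s) - _lf(eta_s + 1)
              + _logq(er_s + kappa, nr_s + 1, logq) - _logq(er_s, nr_s, logq))
        d += _lms(Bn, e_in_n) - _lms(B, e_in)

    # partition prior (-sum ln n_r!): sizes always, count terms when B changes
    nr_s = nr[s] if s < B else 0
    d += _lf(nr[r]) - _lf(nr[r] - 1) + _lf(nr_s) - _lf(nr_s + 1)
    if Bn != B:
        d += _lbinom(N - 1, Bn - 1) - _lbinom(N - 1, B - 1)

    for t in range(nt):
        wsum[touched[t]] = 0
    return d


@njit(cache=True)
def apply_move(mode, i, s_new, indptr, indices, weights, selfw, deg,
               b, B, e, er, nr, eta, wsum, touched):
    """Apply the move and keep summaries consistent; returns the new B.
    An emptied block is swapped with label B-1 before shrinking."""
    r = b[i]
    s = s_new
    creates = s == B
    if creates:
        B += 1
        e[s, :B] = 0
        e[:B, s] = 0
        er[s] = 0
        nr[s] = 0
        if mode != MODE_MS:
            eta[s, :] = 0
    nt, _ = _gather(i, indptr, indices, weights, b, wsum, touched)
    u_self = selfw[i]
    kappa = deg[i]
    for tt in range(nt):
        t = touched[tt]
        wt = wsum[t]
        wsum[t] = 0
        if t == r:
            e[r, r] -= 2 * wt
            e[r, s] += wt
            e[s, r] += wt
        elif t == s:
            e[r, s] -= wt
            e[s, r] -= wt
            e[s, s] += 2 * wt
        else:
            e[r, t] -= wt
            e[t, r] -= wt
            e[s, t] += wt
            e[t, s] += wt
    if u_self != 0:
        e[r, r] -= u_self
        e[s, s] += u_self
    er[r] -= kappa
    er[s] += kappa
    nr[r] -= 1
    nr[s] += 1
    if mode != MODE_MS:
        eta[r, deg[i]] -= 1
        eta[s, deg[i]] += 1
    b[i] = s
    if nr[r] == 0:
        last = B - 1
        if r != last:
            for x in range(b.shape[0]):
                if b[x] == last:
                    b[x] = r
            for t in range(B):
                e[r, t] = e[last, t]
                e[t, r] = e[t, last]
            e[r, r] = e[last, last]
            er[r] = er[last]
            nr[r] = nr[last]
            if mode != MODE_MS:
                eta[r, :] = eta[last, :]
        e[last, :B] = 0
        e[:B, last] = 0
        er[last] = 0
        nr[last] = 0
        if mode != MODE_MS:
            eta[last, :] = 0
        B -= 1
    return B


@njit(cache=True)
def delta_merge(mode, r, s, N, E, B, e, er, nr, eta, logq):
    """Exact objective change of merging block r into block s (r != s)."""
    d = 0.0
    Bn = B - 1
    if mode == MODE_DC:
        old = 0.0
        new = 0.0
        for t in range(B):
            if t == r or t == s:
                continue
            old += _lf(e[r, t]) + _lf(e[s, t])
            new += _lf(e[r, t] + e[s, t])
        old += _lf(e[r, s]) + _ldf(e[r, r]) + _ldf(e[s, s])
        new += _ldf(e[r, r] + e[s, s] + 2 * e[r, s])
        old -= _lf(er[r]) + _lf(er[s])
        new -= _lf(er[r] + er[s])
        d -= new - old
        d += _lf(nr[r] + nr[s]) - _lf(nr[r]) - _lf(nr[s])
        d += _logq(er[r] + er[s], nr[r] + nr[s], logq)
        d -= _logq(er[r], nr[r], logq) + _logq(er[s], nr[s], logq)
        for k in range(eta.shape[1]):
            a = eta[r, k]
            c = eta[s, k]
            if a > 0 and c > 0:
                d -= _lf(a + c) - _lf(a) - _lf(c)
        d += _closure(Bn, E) - _closure(B, E)
    elif mode == MODE_MS:
        old = 0.0
        new = 0.0
        mr = nr[r]
        ms = nr[s]
        for t in range(B):
            if t == r or t == s:
                continue
            mt = nr[t]
            old += _lms(mr * mt, e[r, t]) + _lms(ms * mt, e[s, t])
            new += _lms((mr + ms) * mt, e[r, t] + e[s, t])
        old += _lms(mr * ms, e[r, s])
        old += _lms(mr * (mr + 1) // 2, e[r, r] // 2)
        old += _lms(ms * (ms + 1) // 2, e[s, s] // 2)
        new += _lms((mr + ms) * (mr + ms + 1) // 2,
                    (e[r, r] + e[s, s] + 2 * e[r, s]) // 2)
        d += new - old
        d += _closure(Bn, E) - _closure(B, E)
    else:  # MODE_PP
        e_in = 0
        for t in range(B):
            e_in += e[t, t]
        e_in //= 2
        e_out = E - e_in
        e_in_n = e_in + e[r, s]
        e_out_n = E - e_in_n
        old = _ldf(e[r, r]) + _ldf(e[s, s]) + _lf(e_out)
        new = _ldf(e[r, r] + e[s, s] + 2 * e[r, s]) + _lf(e_out_n)
        old -= _lf(er[r]) + _lf(er[s])
        new -= _lf(er[r] + er[s])
        if B > 1:
            old -= e_out * math.log(B * (B - 1) / 2.0)
        if Bn > 1:
            new -= e_out_n * math.log(Bn * (Bn - 1) / 2.0)
        d -= new - old
        d += _lf(nr[r] + nr[s]) - _lf(nr[r]) - _lf(nr[s])
        d += _logq(er[r] + er[s], nr[r] + nr[s], logq)
        d -= _logq(er[r], nr[r], logq) + _logq(er[s], nr[s], logq)
        for k in range(eta.shape[1]):
            a = eta[r, k]
            c = eta[s, k]
            if a > 0 and c > 0:
                d -= _lf(a + c) - _lf(a) - _lf(c)
        d += _lms(Bn, e_in_n) - _lms(B, e_in)
    # partition prior: -sum ln n_r! loses the two old size terms
    d += _lf(nr[r]) + _lf(nr[s]) - _lf(nr[r] + nr[s])
    d += _lbinom(N - 1, Bn - 1) - _lbinom(N - 1, B - 1)
    return d


@njit(cache=True)
def apply_merge(mode, r, s, b, B, e, er, nr, eta):
    for t in range(B):
        if t != r and t != s:
            e[s, t] += e[r, t]
            e[t, s] += e[t, r]
    e[s, s] += e[r, r] + 2 * e[r, s]
    er[s] += er[r]
    nr[s] += nr[r]
    if mode != MODE_MS:
        eta[s, :] += eta[r, :]
    for x in range(b.shape[0]):
        if b[x] == r:
            b[x] = s
    last = B - 1
    if r != last:
        for x in range(b.shape[0]):
            if b[x] == last:
                b[x] = r
        for t in range(B):
            e[r, t] = e[last, t]
            e[t, r] = e[t, last]
        e[r, r] = e[last, last]
        er[r] = er[last]
        nr[r] = nr[last]
        if mode != MODE_MS:
            eta[r, :] = eta[last, :]
    e[last, :B] = 0
    e[:B, last] = 0
    er[last] = 0
    nr[last] = 0
    if mode != MODE_MS:
        eta[last, :] = 0
    return B - 1


@njit(cache=True)
def _greedy_sweep(mode, N, E, indptr, indices, weights, selfw, deg, b, B,
                  e, er, nr, eta, logq, wsum, touched, cand, order, allow_new):
    moved = 0
    total = 0.0
    for oi in range(order.shape[0]):
        i = order[oi]
        r = b[i]
        ncand = 0
        for p in range(indptr[i], indptr[i + 1]):
            t = b[indices[p]]
            dup = False
            for c in range(ncand):
                if cand[c] == t:
                    dup = True
                    break
            if not dup and t != r:
                cand[ncand] = t
                ncand += 1
        t = np.random.randint(0, B)
        dup = t == r
        for c in range(ncand):
            if cand[c] == t:
                dup = True
        if not dup:
            cand[ncand] = t
            ncand += 1
        if allow_new and nr[r] > 1 and B < b.shape[0]:
            cand[ncand] = B
            ncand += 1
        best = 0.0
        best_s = -1
        for c in range(ncand):
            dd = delta_move(mode, i, cand[c], N, E, indptr, indices, weights,
                            selfw, deg, b, B, e, er, nr, eta, logq, wsum, touched)
            if dd < best - _EPS:
                best = dd
                best_s = cand[c]
        if best_s >= 0:
            B = apply_move(mode, i, best_s, indptr, indices, weights, selfw,
                           deg, b, B, e, er, nr, eta, wsum, touched)
            moved += 1
            total += best
    return B, moved, total


@njit(cache=True)
def _mh_sweep(mode, beta, N, E, indptr, indices, weights, selfw, deg, b, B,
              e, er, nr, eta, logq, wsum, touched, order):
    """Single-node Metropolis-Hastings sweep at inverse temperature beta.

    Proposal: uniform over the B+1 candidate labels (existing blocks plus a
    fresh one); the Hastings factor (B+1)/(B'+1) accounts for the label
    count changing when a block is created or emptied."""
    accepted = 0
    total = 0.0
    for oi in range(order.shape[0]):
        i = order[oi]
        r = b[i]
        s = np.random.randint(0, B + 1)
        if s == r:
            continue
        if s == B and (nr[r] == 1 or B >= b.shape[0]):
            continue
        dd = delta_move(mode, i, s, N, E, indptr, indices, weights, selfw,
                        deg, b, B, e, er, nr, eta, logq, wsum, touched)
        Bn = B + (1 if s == B else 0) - (1 if nr[r] == 1 else 0)
        log_acc = -beta * dd + math.log((B + 1.0) / (Bn + 1.0))
        if log_acc >= 0.0 or math.log(np.random.random()) < log_acc:
            B = apply_move(mode, i, s, indptr, indices, weights, selfw,
                           deg, b, B, e, er, nr, eta, wsum, touched)
            accepted += 1
            total += dd
    return B, accepted, total


@njit(cache=True)
def _merge_pass(mode, N, E, b, B, e, er, nr, eta, logq, n_cand):
    """One randomized pass of greedy pairwise merges; returns new B and the
    number of merges applied.  Candidate targets are reservoir-sampled from
    the blocks connected to the source, plus one uniform block."""
    merged = 0
    picks = np.empty(n_cand + 1, dtype=np.int64)
    r = 0
    while r < B:
        npick = 0
        seen = 0
        for t in range(B):
            if t == r or e[r, t] == 0:
                continue
            seen += 1
            if npick < n_cand:
                picks[npick] = t
                npick += 1
            else:
                j = np.random.randint(0, seen)
                if j < n_cand:
                    picks[j] = t
        if B > 1:
            t = np.random.randint(0, B)
            if t != r:
                dup = False
                for c in range(npick):
                    if picks[c] == t:
                        dup = True
                if not dup:
                    picks[npick] = t
                    npick += 1
        best = 0.0
        best_s = -1
        for c in range(npick):
            dd = delta_merge(mode, r, picks[c], N, E, B, e, er, nr, eta, logq)
            if dd < best - _EPS:
                best = dd
                best_s = picks[c]
        if best_s >= 0:
            B = apply_merge(mode, r, best_s, b, B, e, er, nr, eta)
            merged += 1
            # stay on the same index (a different block was swapped in)
        else:
            r += 1
    return B, merged


@njit(cache=True)
def _merge_nocompact(mode, r, s, b, B, e, er, nr, eta):
    """Merge r into s leaving a dead (zeroed) block r; labels untouched in
    ``b`` (the caller rewrites them through its forwarding map)."""
    for t in range(B):
        if t != r and t != s:
            e[s, t] += e[r, t]
            e[t, s] += e[t, r]
    e[s, s] += e[r, r] + 2 * e[r, s]
    er[s] += er[r]
    nr[s] += nr[r]
    if mode != MODE_MS:
        eta[s, :] += eta[r, :]
    e[r, :B] = 0
    e[:B, r] = 0
    er[r] = 0
    nr[r] = 0
    if mode != MODE_MS:
        eta[r, :] = 0


@njit(cache=True)
def forced_merge(mode, seed, target_B, N, E, b, B, e, er, nr, eta, logq, n_cand):
    """Agglomerate to at most ``target_B`` alive blocks by repeatedly
    applying the least-cost candidate merges, even when their delta is
    positive (the ladder escapes the positive-delta barrier around the
    singleton start).  Dead blocks keep their labels; ``b`` is rewritten
    through a forwarding map after each pass.  Returns the number of alive
    blocks; the caller compacts labels and rebuilds summaries."""
    np.random.seed(seed)
    alive = 0
    for r in range(B):
        if nr[r] > 0:
            alive += 1
    picks = np.empty(n_cand + 1, dtype=np.int64)
    while alive > target_B:
        best_d = np.full(B, np.inf)
        best_t = np.full(B, -1, dtype=np.int64)
        for r in range(B):
            if nr[r] == 0:
                continue
            npick = 0
            seen = 0
            for t in range(B):
                if t == r or nr[t] == 0 or e[r, t] == 0:
                    continue
                seen += 1
                if npick < n_cand:
                    picks[npick] = t
                    npick += 1
                else:
                    j = np.random.randint(0, seen)
                    if j < n_cand:
                        picks[j] = t
            # one random alive block keeps disconnected components mergeable
            for _ in range(4):
                t = np.random.randint(0, B)
                if t != r and nr[t] > 0:
                    picks[npick] = t
                    npick += 1
                    break
            for c in range(npick):
                dd = delta_merge(mode, r, picks[c], N, E, B, e, er, nr, eta, logq)
                if dd < best_d[r]:
                    best_d[r] = dd
                    best_t[r] = picks[c]
        order = np.argsort(best_d)
        into = np.full(B, -1, dtype=np.int64)
        quota = alive - target_B
        applied = 0
        for oi in range(order.shape[0]):
            if quota <= 0:
                break
            r = order[oi]
            if nr[r] == 0 or best_t[r] < 0:
                continue
            t = best_t[r]
            while into[t] >= 0:
                t = into[t]
            if t == r or nr[t] == 0:
                continue
            _merge_nocompact(mode, r, t, b, B, e, er, nr, eta)
            into[r] = t
            alive -= 1
            quota -= 1
            applied += 1
        if applied == 0:
            # degenerate safety net: merge the first two alive blocks
            r0 = -1
            for r in range(B):
                if nr[r] > 0:
                    if r0 < 0:
                        r0 = r
                    else:
                        _merge_nocompact(mode, r0, r, b, B, e, er, nr, eta)
                        into[r0] = r
                        alive -= 1
                        break
        for x in range(b.shape[0]):
            t = b[x]
            while into[t] >= 0:
                t = into[t]
            b[x] = t
    return alive


@njit(cache=True)
def fit_kernel(mode, seed, beta, n_mh_sweeps, max_sweeps, patience,
               N, E, indptr, indices, weights, selfw, deg, b,
               e, er, nr, eta, logq, lfact_k_sum, use_merges, allow_new):
    """Refine a flat partition in place.

    An optional stochastic phase (single-node MH sweeps at finite beta) is
    followed by greedy node-move sweeps until ``patience`` sweeps bring no
    improvement; with ``use_merges`` every greedy sweep is followed by a
    pass of strictly improving block merges.  Merges are disabled during
    the agglomerative ladder: from an unstructured partition, improving
    merges cascade straight to one block, skipping the intermediate scales
    the ladder exists to visit."""
    np.random.seed(seed)
    Bcap = b.shape[0]
    B = 0
    for i in range(N):
        if b[i] + 1 > B:
            B = b[i] + 1
    wsum = np.zeros(Bcap + 1, dtype=np.int64)
    touched = np.empty(Bcap + 1, dtype=np.int64)
    cand = np.empty(Bcap + 2, dtype=np.int64)

    if beta > 0 and not math.isinf(beta):
        for _ in range(n_mh_sweeps):
            order = np.random.permutation(N)
            B, _, _ = _mh_sweep(mode, beta, N, E, indptr, indices, weights,
                                selfw, deg, b, B, e, er, nr, eta, logq,
                                wsum, touched, order)

    stall = 0
    sweeps = 0
    while stall < patience and sweeps < max_sweeps:
        order = np.random.permutation(N)
        B, moved, dtot = _greedy_sweep(mode, N, E, indptr, indices, weights,
                                       selfw, deg, b, B, e, er, nr, eta,
                                       logq, wsum, touched, cand, order,
                                       allow_new)
        merged = 0
        if use_merges:
            B, merged = _merge_pass(mode, N, E, b, B, e, er, nr, eta, logq, 5)
        sweeps += 1
        if dtot < -1e-8 or merged > 0:
            stall = 0
        else:
            stall += 1
    sigma = full_objective(mode, N, E, indptr, indices, weights, selfw, deg,
                           b, B, e, er, nr, eta, lfact_k_sum, logq)
    return B, sigma, sweeps
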