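"""Quality scores and model selection on fitted hierarchies.

* cell stability: fraction of non-root hierarchy levels at which a cell's
  max marginal exceeds 1 - 1/B_l;
* cell affinity: softmax of the negated description-length change of
  reassigning one cell to each annotation block, the basis of label
  transfer with an "Unknown" rejection state;
* level selection: either against the random-matrix estimate k-hat (count
  of eigenvalues of the standardised expression matrix beyond the
  Tracy-Widom null) or by maximum absolute Newman modularity;
* evaluation metrics: adjusted Rand index, two-sample KS on degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import ks_2samp

from .consensus import ConsensusResult
from .preprocess import CellGraph, ExpressionMatrix
from .sbm import NestedPartition, NestedState, _compact, _level0_matrix

__all__ = [
    "AffinityMatrix",
    "LevelStats",
    "TransferResult",
    "cell_stability",
    "affinity_matrix",
    "transfer_labels",
    "rmt_khat",
    "compute_level_stats",
    "select_level_k",
    "select_level_q",
    "modularity",
    "adjusted_rand_index",
    "ks_degree_test",
]

# Tracy-Widom (beta=1) upper quantiles, as tabulated for principal-component
# significance testing (Patterson-style thresholds).
_TW1_QUANTILES = {0.05: 0.9793, 0.01: 2.0234, 0.001: 3.2724}


def cell_stability(consensus: ConsensusResult) -> np.ndarray:
    """Per-cell stability S in [0, 1].

    S_c is the fraction of hierarchy levels with at least two groups at
    which the cell's maximum marginal probability strictly exceeds
    1 - 1/B_l.  The root (B = 1) never counts; a consensus without any
    multi-group level has no defined stability.
    """
    eligible = [l for l in range(consensus.n_levels) if consensus.block_counts[l] >= 2]
    if not eligible:
        raise ValueError("cell stability undefined: no level with >= 2 groups")
    n = consensus.marginals[0].shape[0]
    hits = np.zeros(n)
    for l in eligible:
        B = consensus.block_counts[l]
        mx = consensus.marginals[l].max(axis=1)
        hits += (mx > 1.0 - 1.0 / B).astype(float)
    return hits / len(eligible)


@dataclass
class AffinityMatrix:
    """Row-stochastic cell x annotation-label affinities."""

    values: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def argmax_labels(self) -> list[str]:
        return [self.columns[i] for i in np.argmax(self.values, axis=1)]

    def ranking(self) -> np.ndarray:
        """Label indices per cell, best affinity first."""
        return np.argsort(-self.values, axis=1, kind="stable")


def _labels_to_partition(labels) -> tuple[np.ndarray, list[str]]:
    labels = [str(x) for x in labels]
    uniq = sorted(set(labels))
    if "Unknown" in uniq:  # keep the rejection state last, order recorded
        uniq = [u for u in uniq if u != "Unknown"] + ["Unknown"]
    index = {u: i for i, u in enumerate(uniq)}
    return np.array([index[x] for x in labels], dtype=np.int64), uniq


def affinity_matrix(g: CellGraph, labels) -> AffinityMatrix:
    """Entropy-based affinity of every cell to every annotation label.

    The annotation (including "Unknown" if present) is taken as a flat
    partition of the graph; for each cell the description-length change
    dSigma of moving it into each block is evaluated exactly (zero for its
    current block), and the row affinity is softmax(-dSigma).
    """
    labels = list(labels)
    if len(labels) != g.n_nodes:
        raise ValueError("labels must cover every node of the graph")
    b, columns = _labels_to_partition(labels)
    state = NestedState(g, b)
    n_blocks = len(columns)
    delta = np.zeros((g.n_nodes, n_blocks))
    for c in range(g.n_nodes):
        for r in range(n_blocks):
            delta[c, r] = state.delta_dl_move(0, c, r)
    scores = -delta
    scores -= scores.max(axis=1, keepdims=True)
    aff = np.exp(scores)
    aff /= aff.sum(axis=1, keepdims=True)
    return AffinityMatrix(aff, columns)


@dataclass
class TransferResult:
    labels: list[str]
    affinity: AffinityMatrix
    ranking: np.ndarray  # label indices per cell, best first


def transfer_labels(
    g: CellGraph, labels, unknown_token: str = "Unknown", max_iter: int = 20
) -> TransferResult:
    """Assign annotation labels to "Unknown" cells by highest affinity.

    Only cells currently carrying ``unknown_token`` are ever reassigned;
    each goes to its argmax-affinity label, which may be ``unknown_token``
    itself when the evidence does not support any annotated group.
    Annotated cells never change.

    The assignment is iterated to a fixed point (at most ``max_iter``
    rounds): reassigned cells stop propping up the residual "Unknown"
    block, letting coherent query sub-clusters drain into their true
    group, while cells without evidence (e.g. isolated nodes) keep
    rejecting every annotated label.  ``max_iter=1`` gives the single-shot
    assignment.  The returned affinity matrix and ranking are the ones at
    the fixed point.
    """
    labels = [str(x) for x in labels]
    out = list(labels)
    if unknown_token not in labels:
        aff = affinity_matrix(g, labels)
        return TransferResult(out, aff, aff.ranking())
    unknown_idx = [i for i, l in enumerate(labels) if l == unknown_token]
    aff = affinity_matrix(g, out)
    for _ in range(max_iter):
        best = aff.argmax_labels()
        changed = 0
        for i in unknown_idx:
            if out[i] == unknown_token and best[i] != unknown_token:
                out[i] = best[i]
                changed += 1
        if changed == 0:
            break
        aff = affinity_matrix(g, out)
    return TransferResult(out, aff, aff.ranking())


def rmt_khat(X: ExpressionMatrix, alpha: float = 0.001) -> int:
    """Number of significant eigenvalues of the standardised expression.

    Genes are standardised to zero mean and unit sample variance (constant
    genes are dropped with a warning); the eigenvalues of Z'Z are compared
    against the Tracy-Widom (beta=1) null after Marchenko-Pastur
    centering mu = (sqrt(n-1) + sqrt(p))^2 and scaling
    sqrt(mu) * (1/sqrt(n-1) + 1/sqrt(p))^(1/3).  k-hat counts eigenvalues
    whose standardised statistic exceeds the upper 1-alpha TW quantile.
    """
    if X.layer != "lognorm":
        raise ValueError("rmt_khat expects the lognorm layer")
    if X.n_cells < 2:
        raise ValueError("need at least two cells")
    if alpha not in _TW1_QUANTILES:
        raise ValueError(f"alpha must be one of {sorted(_TW1_QUANTILES)}")
    vals = X.values
    sd = vals.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant genes")
    vals = vals[:, keep]
    if vals.shape[1] == 0:
        raise ValueError("no variable genes left")
    z = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)
    n, p = z.shape
    gram = z @ z.T if n <= p else z.T @ z
    lam = np.linalg.eigvalsh(gram)
    mu = (np.sqrt(n - 1) + np.sqrt(p)) ** 2
    scale = np.sqrt(mu) * (1 / np.sqrt(n - 1) + 1 / np.sqrt(p)) ** (1 / 3)
    stat = (lam - mu) / scale
    return int((stat > _TW1_QUANTILES[alpha]).sum())


@dataclass
class LevelStats:
    """Per-level block counts and modularities plus selection results."""

    B: list[int]
    Q: list[float]
    k_hat: int | None = None
    i_k: int | None = None
    i_q: int | None = None


def modularity(g: CellGraph, b: np.ndarray) -> float:
    """Newman modularity of a flat partition (gamma = 1)."""
    b = _compact(np.asarray(b))
    E = g.n_edges
    if E == 0:
        return 0.0
    e = _level0_matrix(g, b, int(b.max()) + 1)
    within = e.diagonal() / (2.0 * E)
    degsum = e.sum(axis=1) / (2.0 * E)
    return float((within - degsum**2).sum())


def compute_level_stats(
    g: CellGraph,
    partition: NestedPartition,
    X: ExpressionMatrix | None = None,
    k_hat: int | None = None,
    alpha: float = 0.001,
) -> LevelStats:
    """B_x and Q_x for every hierarchy level; runs the selections that the
    available inputs allow (k-hat needs the expression matrix)."""
    B = [int(partition.project(l).max()) + 1 for l in range(partition.n_levels)]
    Q = [modularity(g, partition.project(l)) for l in range(partition.n_levels)]
    if k_hat is None and X is not None:
        k_hat = rmt_khat(X, alpha=alpha)
    stats = LevelStats(B=B, Q=Q, k_hat=k_hat)
    stats.i_q = _argbest([abs(q) for q in Q], maximise=True)
    if k_hat is not None:
        stats.i_k = select_level_k(stats)
    return stats


def _argbest(values: list[float], maximise: bool) -> int:
    # ties broken toward the coarser level (largest index)
    best_i = 0
    for i, v in enumerate(values):
        cur = values[best_i]
        if (v > cur if maximise else v < cur) or v == cur:
            best_i = i
    return best_i


def select_level_k(stats: LevelStats) -> int:
    """Level whose block count is closest to k-hat (ties -> coarser)."""
    if stats.k_hat is None:
        raise ValueError("k_hat has not been computed")
    return _argbest([abs(b - stats.k_hat) for b in stats.B], maximise=False)


def select_level_q(
    g: CellGraph, b: NestedPartition
) -> tuple[int, list[float]]:
    """Level of maximum |Q| (ties -> coarser), with Q per level."""
    Q = [modularity(g, b.project(l)) for l in range(b.n_levels)]
    return _argbest([abs(q) for q in Q], maximise=True), Q


def adjusted_rand_index(p1, p2) -> float:
    """Permutation-model adjusted Rand index between two flat partitions."""
    from sklearn.metrics import adjusted_rand_score

    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("partitions cover different numbers of cells")
    return float(adjusted_rand_score(p1, p2))


def ks_degree_test(g1: CellGraph, g2: CellGraph) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on the degree sequences."""
    if g1.n_nodes == 0 or g2.n_nodes == 0:
        raise ValueError("graphs must be non-empty")
    res = ks_2samp(g1.degrees(), g2.degrees(), method="asymp")
    return float(res.statistic), float(res.pvalue)
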