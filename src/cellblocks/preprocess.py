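"""From raw counts to a cell kNN graph, plus the perturbation operators.

This module owns the two central containers (:class:`ExpressionMatrix` and
:class:`CellGraph`), the standard single-cell preprocessing steps
(filtering, total-count normalisation + log1p, PCA, kNN graph construction)
and the two perturbations used to probe the block model's null behaviour:
degree-preserving edge shuffling and per-gene white-noise injection.

File formats are handled by established readers: MatrixMarket via
``scipy.io``, H5AD via :mod:`anndata`, GraphML via :mod:`networkx`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "ExpressionMatrix",
    "CellGraph",
    "filter_cells_genes",
    "normalize_log",
    "pca_embed",
    "build_knn_graph",
    "shuffle_edges",
    "add_white_noise",
    "read_mtx",
    "read_dense_csv",
    "read_h5ad",
    "read_graph",
]


@dataclass
class ExpressionMatrix:
    """A cells x genes matrix with identifiers and a layer tag.

    ``layer`` is ``"raw"`` for count data (all values >= 0) or ``"lognorm"``
    for normalised, log1p-transformed data.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x genes matrix")
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError("row count does not match number of cell ids")
        if self.values.shape[1] != len(self.gene_ids):
            raise ValueError("column count does not match number of gene ids")
        if self.layer not in ("raw", "lognorm"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.layer == "raw" and (self.values < 0).any():
            raise ValueError("raw layer must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class CellGraph:
    """Undirected simple graph over cells.

    ``edges`` is an (E, 2) integer array with each unordered pair stored once
    as (u, v), u < v; no self-loops, no duplicates.
    """

    n_nodes: int
    edges: np.ndarray
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        e = np.sort(e, axis=1)
        if e.shape[0]:
            if e.min() < 0 or e.max() >= self.n_nodes:
                raise ValueError("edge endpoint outside [0, n_nodes)")
            if (e[:, 0] == e[:, 1]).any():
                raise ValueError("self-loops are not allowed")
            order = np.lexsort((e[:, 1], e[:, 0]))
            e = e[order]
            if (np.diff(e, axis=0) == 0).all(axis=1).any():
                raise ValueError("duplicate edges are not allowed")
        self.edges = e
        if self.node_ids is not None and len(self.node_ids) != self.n_nodes:
            raise ValueError("node_ids length must equal n_nodes")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def adjacency_lists(self) -> list[np.ndarray]:
        nbr: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for u, v in self.edges:
            nbr[u].append(v)
            nbr[v].append(u)
        return [np.array(sorted(x), dtype=np.int64) for x in nbr]

    def to_edge_list_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\n")
            for u, v in self.edges:
                fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def filter_cells_genes(
    X: ExpressionMatrix, min_genes: int = 200, min_cells: int = 3
) -> ExpressionMatrix:
    """Drop low-complexity cells, then rarely detected genes.

    A cell is kept when it has at least ``min_genes`` genes with value > 0;
    afterwards a gene is kept when it is > 0 in at least ``min_cells`` of the
    retained cells.  Cells are filtered first, then genes (so a gene's
    support is counted on the surviving cells only).
    """
    if X.layer != "raw":
        raise ValueError("filter_cells_genes expects the raw layer")
    keep_cells = (X.values > 0).sum(axis=1) >= min_genes
    if not keep_cells.any():
        raise ValueError("empty matrix: all cells removed by filtering")
    vals = X.values[keep_cells]
    keep_genes = (vals > 0).sum(axis=0) >= min_cells
    if not keep_genes.any():
        raise ValueError("empty matrix: all genes removed by filtering")
    return ExpressionMatrix(
        vals[:, keep_genes],
        [c for c, k in zip(X.cell_ids, keep_cells) if k],
        [g for g, k in zip(X.gene_ids, keep_genes) if k],
        layer="raw",
    )


def normalize_log(X: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then ln(1 + x)."""
    if X.layer != "raw":
        raise ValueError("normalize_log expects the raw layer")
    totals = X.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell {X.cell_ids[zero[0]]!r} has zero total count; cannot normalise"
        )
    scaled = X.values * (target_sum / totals)[:, None]
    return ExpressionMatrix(
        np.log1p(scaled), list(X.cell_ids), list(X.gene_ids), layer="lognorm"
    )


def pca_embed(X: ExpressionMatrix, n_comps: int = 50, seed: int = 0) -> np.ndarray:
    """PCA embedding (cells x n_comps), components ordered by explained variance.

    Uses the deterministic full SVD solver, so the result is reproducible
    bit-for-bit for a given input regardless of the seed; the seed is kept in
    the signature for interface stability.
    """
    from sklearn.decomposition import PCA

    if X.layer != "lognorm":
        raise ValueError("pca_embed expects the lognorm layer")
    if not (0 < n_comps < min(X.n_cells, X.n_genes)):
        raise ValueError(
            f"n_comps={n_comps} out of range for a {X.n_cells}x{X.n_genes} matrix"
        )
    pca = PCA(n_components=n_comps, svd_solver="full", random_state=seed)
    return pca.fit_transform(X.values)


def build_knn_graph(emb: np.ndarray, n_neighbors: int = 15) -> CellGraph:
    """Euclidean kNN graph, symmetrised by union into a simple graph.

    Each point is linked to its ``n_neighbors`` nearest other points; the
    directed relation is symmetrised by union (an edge exists if either end
    lists the other).  Distance ties are broken by ascending point index
    (stable sort), which makes the graph deterministic.
    """
    emb = np.asarray(emb, dtype=float)
    n = emb.shape[0]
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    if n < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} points, got {n}")
    dist = cdist(emb, emb)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")[:, :n_neighbors]
    pairs = set()
    for i in range(n):
        for j in order[i]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    edges = np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
    return CellGraph(n, edges)


# ---------------------------------------------------------------------------
# Perturbation operators
# ---------------------------------------------------------------------------


def shuffle_edges(g: CellGraph, seed: int = 0, mode: str = "swap") -> CellGraph:
    """Randomise edge endpoints while keeping the node set and |E|.

    ``mode="swap"`` (default) performs degree-preserving double-edge swaps:
    10 x |E| successful swaps, rejecting any swap that would create a
    self-loop or a duplicate edge, so the degree multiset is conserved
    exactly.  ``mode="relabel"`` re-pairs the endpoint pool uniformly
    (configuration-model style), which also conserves degrees but mixes
    faster per draw; conflicting pairs are re-drawn.
    """
    if g.n_edges < 2:
        raise ValueError("need at least two edges to shuffle")
    rng = np.random.default_rng(seed)
    if mode == "relabel":
        return _shuffle_relabel(g, rng)
    if mode != "swap":
        raise ValueError(f"unknown mode {mode!r}")
    edges = [tuple(e) for e in g.edges]
    present = set(edges)
    target = 10 * len(edges)
    done = 0
    attempts = 0
    max_attempts = 200 * len(edges) + 1000
    while done < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, d) and (c, b)
        e1 = (min(a, d), max(a, d))
        e2 = (min(c, b), max(c, b))
        if a == d or c == b or e1 in present or e2 in present or e1 == e2:
            continue
        present.discard(edges[i])
        present.discard(edges[j])
        present.add(e1)
        present.add(e2)
        edges[i], edges[j] = e1, e2
        done += 1
    return CellGraph(g.n_nodes, np.array(sorted(present), dtype=np.int64), g.node_ids)


def _shuffle_relabel(g: CellGraph, rng: np.random.Generator) -> CellGraph:
    stubs = g.edges.ravel().copy()
    pairs: set[tuple[int, int]] = set()
    remaining = stubs
    for _ in range(200):
        rng.shuffle(remaining)
        left = []
        for k in range(0, len(remaining) - 1, 2):
            u, v = int(remaining[k]), int(remaining[k + 1])
            e = (min(u, v), max(u, v))
            if u == v or e in pairs:
                left.extend((u, v))
            else:
                pairs.add(e)
        if not left:
            break
        remaining = np.array(left, dtype=np.int64)
    else:
        raise RuntimeError("could not resolve endpoint conflicts while relabelling")
    return CellGraph(g.n_nodes, np.array(sorted(pairs), dtype=np.int64), g.node_ids)


def add_white_noise(X: ExpressionMatrix, k: float, seed: int = 0) -> ExpressionMatrix:
    """Add per-gene Gaussian noise N(mu_g, (k sigma_g)^2) to every value.

    mu_g and sigma_g are the mean and sample (ddof=1) standard deviation of
    the gene's *non-zero* log-normalised values; genes with fewer than two
    non-zero values get sigma_g = 0.  With k = 0 the operation degenerates to
    adding mu_g to each entry of gene g.
    """
    if X.layer != "lognorm":
        raise ValueError("add_white_noise expects the lognorm layer")
    if k < 0:
        raise ValueError("noise multiplier k must be >= 0")
    rng = np.random.default_rng(seed)
    vals = X.values
    mu = np.zeros(X.n_genes)
    sigma = np.zeros(X.n_genes)
    for gidx in range(X.n_genes):
        nz = vals[:, gidx][vals[:, gidx] != 0]
        if nz.size >= 1:
            mu[gidx] = nz.mean()
        if nz.size >= 2:
            sigma[gidx] = nz.std(ddof=1)
    noise = mu[None, :] + k * sigma[None, :] * rng.standard_normal(vals.shape)
    return ExpressionMatrix(
        vals + noise, list(X.cell_ids), list(X.gene_ids), layer="lognorm"
    )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_mtx(
    mtx_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
    cells_in_columns: bool = True,
) -> ExpressionMatrix:
    """MatrixMarket triplet + barcodes/features TSVs (10x layout).

    10x convention stores genes in rows and cells in columns; set
    ``cells_in_columns=False`` if the matrix is already cells x genes.
    """
    from scipy.io import mmread

    mat = mmread(str(mtx_path))
    mat = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    features = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str).tolist()
    if cells_in_columns:
        mat = mat.T
    return ExpressionMatrix(mat, barcodes, features, layer="raw")


def read_dense_csv(path: str | Path, sep: str | None = None) -> ExpressionMatrix:
    """Dense CSV/TSV with cells in rows, genes in columns, both labelled."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        df.index.astype(str).tolist(),
        df.columns.astype(str).tolist(),
        layer="raw",
    )


def read_h5ad(path: str | Path, layer: str = "raw") -> ExpressionMatrix:
    import anndata as ad

    adata = ad.read_h5ad(str(path))
    mat = adata.X
    if hasattr(mat, "toarray"):
        mat = mat.toarray()
    return ExpressionMatrix(
        np.asarray(mat, dtype=float),
        adata.obs_names.astype(str).tolist(),
        adata.var_names.astype(str).tolist(),
        layer=layer,
    )


def read_graph(path: str | Path) -> CellGraph:
    """Edge-list TSV (header ``source<TAB>target``, 0-based ids) or GraphML."""
    path = Path(path)
    if path.suffix == ".graphml":
        import networkx as nx

        gx = nx.read_graphml(str(path))
        nodes = sorted(gx.nodes())
        index = {n: i for i, n in enumerate(nodes)}
        edges = [(index[u], index[v]) for u, v in gx.edges() if u != v]
        return CellGraph(len(nodes), np.array(sorted(set(
            (min(u, v), max(u, v)) for u, v in edges)), dtype=np.int64),
            [str(n) for n in nodes])
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["source", "target"]:
        raise ValueError("edge-list TSV must have a 'source<TAB>target' header")
    edges = df.iloc[:, :2].to_numpy(dtype=np.int64)
    n_nodes = int(edges.max()) + 1 if edges.size else 0
    return CellGraph(n_nodes, edges)
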