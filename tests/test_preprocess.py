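"""Filtering, normalisation, embedding, kNN graphs and perturbations."""

import numpy as np
import pytest

from cellblocks import (
    CellGraph,
    ExpressionMatrix,
    add_white_noise,
    build_knn_graph,
    filter_cells_genes,
    normalize_log,
    pca_embed,
    shuffle_edges,
)
from cellblocks.preprocess import (
    read_dense_csv,
    read_graph,
    read_h5ad,
    read_mtx,
)
from cellblocks.scoring import ks_degree_test


def _em(values, layer="raw"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"c{i}" for i in range(values.shape[0])],
        [f"g{j}" for j in range(values.shape[1])],
        layer=layer,
    )


class TestFilter:
    def test_cell_below_min_genes_removed(self):
        rng = np.random.default_rng(0)
        vals = rng.poisson(2.0, size=(5, 300)) + 1.0  # everything detected
        vals[0, 199:] = 0.0  # cell 0 has exactly 199 nonzero genes
        out = filter_cells_genes(_em(vals), min_genes=200, min_cells=1)
        assert out.n_cells == 4 and "c0" not in out.cell_ids

    def test_conforming_matrix_unchanged(self):
        vals = np.ones((4, 5))
        out = filter_cells_genes(_em(vals), min_genes=2, min_cells=2)
        assert np.array_equal(out.values, vals)
        assert out.cell_ids == [f"c{i}" for i in range(4)]

    def test_gene_below_min_cells_removed(self):
        # 3 cells x 2 genes, gene B nonzero in 2 cells only
        vals = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 0.0]])
        out = filter_cells_genes(_em(vals), min_genes=1, min_cells=3)
        assert out.n_genes == 1 and out.gene_ids == ["g0"]

    def test_empty_result_raises(self):
        with pytest.raises(ValueError, match="empty matrix"):
            filter_cells_genes(_em(np.zeros((3, 3))), min_genes=1, min_cells=1)

    def test_idempotent_on_conforming_input(self):
        rng = np.random.default_rng(1)
        X = _em(rng.poisson(3.0, size=(20, 30)).astype(float))
        once = filter_cells_genes(X, 5, 3)
        twice = filter_cells_genes(once, 5, 3)
        assert np.array_equal(once.values, twice.values)


class TestNormalize:
    def test_hand_computed_example(self):
        out = normalize_log(_em([[10.0, 0.0]]), target_sum=10)
        assert np.allclose(out.values, [[np.log(11.0), 0.0]])
        assert out.layer == "lognorm"

    def test_equal_cells_identical_rows(self):
        out = normalize_log(_em([[2.0, 4.0], [2.0, 4.0]]))
        assert np.array_equal(out.values[0], out.values[1])

    def test_row_totals_hit_target_before_log(self):
        rng = np.random.default_rng(2)
        X = _em(rng.poisson(5.0, size=(10, 50)) + 1.0)
        out = normalize_log(X, target_sum=1e4)
        recovered = np.expm1(out.values).sum(axis=1)
        assert np.allclose(recovered, 1e4)

    def test_zero_count_cell_named_in_error(self):
        with pytest.raises(ValueError, match="c1"):
            normalize_log(_em([[1.0, 2.0], [0.0, 0.0]]))


class TestPCA:
    def test_rank_one_single_component(self):
        u = np.arange(1, 9, dtype=float)[:, None]
        v = np.ones((1, 6))
        X = _em(u @ v, layer="lognorm")
        emb = pca_embed(X, n_comps=1, seed=0)
        centred = X.values - X.values.mean(axis=0)
        assert np.isclose((emb**2).sum(), (centred**2).sum())

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        X = _em(rng.normal(size=(30, 20)), layer="lognorm")
        a = pca_embed(X, n_comps=5, seed=7)
        b = pca_embed(X, n_comps=5, seed=7)
        assert np.array_equal(a, b)

    def test_reconstruction_error_nonincreasing(self):
        rng = np.random.default_rng(4)
        X = _em(rng.normal(size=(40, 30)), layer="lognorm")
        centred = X.values - X.values.mean(axis=0)
        errs = []
        for k in (2, 5, 10):
            emb = pca_embed(X, n_comps=k, seed=0)
            errs.append((centred**2).sum() - (emb**2).sum())
        assert errs[0] >= errs[1] >= errs[2] >= -1e-9

    def test_out_of_range_raises(self):
        X = _em(np.ones((5, 4)), layer="lognorm")
        with pytest.raises(ValueError):
            pca_embed(X, n_comps=4)


class TestKnnGraph:
    def test_two_separated_clouds_stay_disconnected(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, size=(40, 3))
        b = rng.normal(50.0, 1.0, size=(40, 3))  # >> 10 cloud sds apart
        g = build_knn_graph(np.vstack([a, b]), n_neighbors=5)
        cross = [(u, v) for u, v in g.edges if (u < 40) != (v < 40)]
        assert not cross
        # connected components match the clouds exactly
        import networkx as nx

        gx = nx.Graph(list(map(tuple, g.edges)))
        gx.add_nodes_from(range(80))
        comps = sorted(nx.connected_components(gx), key=min)
        assert len(comps) == 2
        assert comps[0] == set(range(40)) and comps[1] == set(range(40, 80))

    def test_tie_break_by_index(self):
        # 3 coincident points (exact distance ties): each picks the
        # lowest-index other point, so the union graph is a star on node 0
        pts = np.zeros((3, 2))
        g = build_knn_graph(pts, n_neighbors=1)
        assert {tuple(e) for e in g.edges} == {(0, 1), (0, 2)}

    def test_edge_count_union_bound(self):
        rng = np.random.default_rng(6)
        emb = rng.normal(size=(50, 4))
        g = build_knn_graph(emb, n_neighbors=7)
        assert g.n_edges <= 50 * 7
        assert g.degrees().min() >= 1

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            build_knn_graph(np.zeros((3, 2)), n_neighbors=3)


class TestShuffleEdges:
    def _graph(self, seed=7, n=60, p=0.15):
        rng = np.random.default_rng(seed)
        edges = [
            (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
        ]
        return CellGraph(n, np.array(edges))

    def test_edge_count_and_degrees_preserved(self):
        g = self._graph()
        shuf = shuffle_edges(g, seed=0)
        assert shuf.n_edges == g.n_edges
        assert np.array_equal(np.sort(shuf.degrees()), np.sort(g.degrees()))
        assert np.array_equal(shuf.degrees(), g.degrees())  # per-node, swaps

    def test_deterministic(self):
        g = self._graph()
        a = shuffle_edges(g, seed=3)
        b = shuffle_edges(g, seed=3)
        assert np.array_equal(a.edges, b.edges)

    def test_actually_rewires(self):
        g = self._graph()
        shuf = shuffle_edges(g, seed=1)
        assert {tuple(e) for e in shuf.edges} != {tuple(e) for e in g.edges}

    def test_ks_on_degrees_is_zero(self):
        g = self._graph()
        D, p = ks_degree_test(g, shuffle_edges(g, seed=2))
        assert D == 0.0 and p == 1.0

    def test_relabel_mode_preserves_degrees(self):
        g = self._graph()
        shuf = shuffle_edges(g, seed=4, mode="relabel")
        assert shuf.n_edges == g.n_edges
        assert np.array_equal(np.sort(shuf.degrees()), np.sort(g.degrees()))

    def test_too_few_edges_raises(self):
        with pytest.raises(ValueError):
            shuffle_edges(CellGraph(2, np.array([[0, 1]])), seed=0)


class TestWhiteNoise:
    def test_k_zero_adds_gene_means(self):
        vals = np.array([[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]])
        out = add_white_noise(_em(vals, layer="lognorm"), k=0.0, seed=0)
        mu = np.array([3.0, 3.0])  # nonzero means per gene
        assert np.allclose(out.values, vals + mu)

    def test_moments_exclude_zeros(self):
        # gene with values (0, 2, 4): mu=3, sigma=sqrt(2) (sample sd)
        vals = np.array([[0.0], [2.0], [4.0]])
        X = _em(vals, layer="lognorm")
        draws = add_white_noise(X, k=1.0, seed=0).values - vals
        # with k=1 the additive noise is N(3, 2); check against many seeds
        samples = np.concatenate(
            [add_white_noise(X, k=1.0, seed=s).values - vals for s in range(300)]
        )
        assert abs(samples.mean() - 3.0) < 0.1
        assert abs(samples.std(ddof=1) - np.sqrt(2.0)) < 0.1

    def test_gene_with_single_nonzero_gets_zero_sd(self):
        vals = np.array([[0.0], [5.0]])
        out = add_white_noise(_em(vals, layer="lognorm"), k=2.0, seed=0)
        assert np.allclose(out.values, vals + 5.0)  # mu=5, sigma=0

    def test_deterministic_and_negative_k_rejected(self):
        rng = np.random.default_rng(8)
        X = _em(rng.random((5, 4)), layer="lognorm")
        assert np.array_equal(
            add_white_noise(X, 1.5, seed=9).values,
            add_white_noise(X, 1.5, seed=9).values,
        )
        with pytest.raises(ValueError):
            add_white_noise(X, -0.1, seed=0)


class TestIO:
    def test_mtx_roundtrip(self, tmp_path):
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        rng = np.random.default_rng(9)
        vals = rng.poisson(1.0, size=(6, 10)).astype(float)
        mmwrite(str(tmp_path / "m.mtx"), csr_matrix(vals.T))  # genes x cells
        (tmp_path / "barcodes.tsv").write_text(
            "\n".join(f"c{i}" for i in range(6)) + "\n"
        )
        (tmp_path / "features.tsv").write_text(
            "\n".join(f"g{j}" for j in range(10)) + "\n"
        )
        X = read_mtx(
            tmp_path / "m.mtx", tmp_path / "barcodes.tsv", tmp_path / "features.tsv"
        )
        assert np.array_equal(X.values, vals)
        assert X.cell_ids == [f"c{i}" for i in range(6)]

    def test_dense_csv_roundtrip(self, tmp_path):
        import pandas as pd

        rng = np.random.default_rng(10)
        vals = rng.poisson(2.0, size=(4, 7)).astype(float)
        df = pd.DataFrame(
            vals, index=[f"c{i}" for i in range(4)], columns=[f"g{j}" for j in range(7)]
        )
        df.to_csv(tmp_path / "m.csv")
        X = read_dense_csv(tmp_path / "m.csv")
        assert np.array_equal(X.values, vals) and X.gene_ids == list(df.columns)

    def test_h5ad_roundtrip(self, tmp_path):
        import anndata as ad

        rng = np.random.default_rng(11)
        vals = rng.poisson(1.5, size=(5, 8)).astype(float)
        adata = ad.AnnData(X=vals)
        adata.obs_names = [f"c{i}" for i in range(5)]
        adata.var_names = [f"g{j}" for j in range(8)]
        adata.write_h5ad(tmp_path / "m.h5ad")
        X = read_h5ad(tmp_path / "m.h5ad")
        assert np.array_equal(X.values, vals)

    def test_edge_list_roundtrip(self, tmp_path):
        g = CellGraph(5, np.array([(0, 1), (1, 2), (3, 4)]))
        g.to_edge_list_tsv(tmp_path / "g.tsv")
        g2 = read_graph(tmp_path / "g.tsv")
        assert np.array_equal(g2.edges, g.edges)

    def test_graphml_read(self, tmp_path):
        import networkx as nx

        gx = nx.Graph([(0, 1), (1, 2), (2, 3)])
        nx.write_graphml(gx, tmp_path / "g.graphml")
        g = read_graph(tmp_path / "g.graphml")
        assert g.n_nodes == 4 and g.n_edges == 3


class TestCellGraphInvariants:
    def test_rejects_self_loops_and_duplicates(self):
        with pytest.raises(ValueError):
            CellGraph(3, np.array([(0, 0)]))
        with pytest.raises(ValueError):
            CellGraph(3, np.array([(0, 1), (1, 0)]))
        with pytest.raises(ValueError):
            CellGraph(2, np.array([(0, 2)]))

    def test_degree_sum_is_twice_edges(self):
        rng = np.random.default_rng(12)
        from _oracles import random_graph

        g = CellGraph(15, random_graph(15, 0.3, rng))
        assert g.degrees().sum() == 2 * g.n_edges
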