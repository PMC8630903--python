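"""Cell stability, affinities and label transfer, level selection, metrics."""

import numpy as np
import pytest

from cellblocks import (
    CellGraph,
    ExpressionMatrix,
    NestedPartition,
    adjusted_rand_index,
    affinity_matrix,
    cell_stability,
    compute_level_stats,
    ks_degree_test,
    modularity,
    rmt_khat,
    select_level_k,
    select_level_q,
    transfer_labels,
)
from cellblocks.consensus import ConsensusResult
from cellblocks.scoring import LevelStats
from cellblocks.synthetic import PlantedSpec, generate_expression, generate_sbm_graph
from cellblocks.preprocess import normalize_log


def _consensus_from_marginals(marginals):
    return ConsensusResult(
        marginals=[np.asarray(M, dtype=float) for M in marginals],
        labels=[np.argmax(M, axis=1) for M in marginals],
        nested_labels=[np.argmax(M, axis=1) for M in marginals],
        block_counts=[np.asarray(M).shape[1] for M in marginals],
        n_models=10,
    )


class TestCellStability:
    def test_certain_cells_score_one(self):
        M = np.zeros((3, 4))
        M[:, 0] = 1.0
        cons = _consensus_from_marginals([M] * 4)
        assert np.array_equal(cell_stability(cons), [1.0, 1.0, 1.0])

    def test_uniform_marginals_score_zero(self):
        # p = 1/B never strictly exceeds 1 - 1/B for B >= 2
        levels = [np.full((5, B), 1.0 / B) for B in (2, 3, 4)]
        cons = _consensus_from_marginals(levels)
        assert np.array_equal(cell_stability(cons), np.zeros(5))

    def test_hand_computed_thresholds(self):
        # levels B=(4,2); cell 0: max-marginals (0.9, 0.6) -> S=1;
        # cell 1: (0.7, 0.6) -> only the B=2 level passes -> S=0.5
        M4 = np.array([[0.9, 0.1 / 3, 0.1 / 3, 0.1 / 3],
                       [0.7, 0.1, 0.1, 0.1]])
        M2 = np.array([[0.6, 0.4], [0.6, 0.4]])
        cons = _consensus_from_marginals([M4, M2])
        assert np.allclose(cell_stability(cons), [1.0, 0.5])

    def test_root_levels_excluded_and_error_without_eligible(self):
        M_root = np.ones((4, 1))
        M2 = np.full((4, 2), 0.5)
        cons = _consensus_from_marginals([M2, M_root])
        assert np.array_equal(cell_stability(cons), np.zeros(4))
        with pytest.raises(ValueError):
            cell_stability(_consensus_from_marginals([M_root]))

    def test_range_invariant(self):
        rng = np.random.default_rng(0)
        levels = []
        for B in (5, 3, 2):
            M = rng.random((20, B))
            M /= M.sum(axis=1, keepdims=True)
            levels.append(M)
        S = cell_stability(_consensus_from_marginals(levels))
        assert (S >= 0).all() and (S <= 1).all()


class TestAffinity:
    def test_clique_cell_keeps_its_label(self, two_cliques6):
        labels = ["A"] * 6 + ["B"] * 6
        aff = affinity_matrix(two_cliques6, labels)
        assert np.allclose(aff.values.sum(axis=1), 1.0, atol=1e-9)
        assert aff.argmax_labels() == labels

    def test_attached_node_prefers_its_clique(self):
        edges = [(i, j) for i in range(6) for j in range(i + 1, 6)]
        edges += [(i + 6, j + 6) for i in range(6) for j in range(i + 1, 6)]
        edges += [(12, i) for i in range(5)]
        g = CellGraph(13, np.array(edges))
        labels = ["A"] * 6 + ["B"] * 6 + ["B"]
        aff = affinity_matrix(g, labels)
        assert aff.argmax_labels()[12] == "A"

    def test_label_count_mismatch_rejected(self, two_cliques6):
        with pytest.raises(ValueError):
            affinity_matrix(two_cliques6, ["A"] * 5)


class TestTransfer:
    def test_without_unknown_is_identity(self, two_cliques6):
        labels = ["A"] * 6 + ["B"] * 6
        res = transfer_labels(two_cliques6, labels)
        assert res.labels == labels

    def test_masked_half_block_recovered(self):
        for seed in range(3):
            g, truth = generate_sbm_graph(
                PlantedSpec(200, [100, 100], 0.2, 0.02, seed=seed)
            )
            labels = ["A" if t == 0 else "B" for t in truth]
            rng = np.random.default_rng(seed + 10)
            masked = rng.choice(100, 50, replace=False) + 100
            for m in masked:
                labels[m] = "Unknown"
            res = transfer_labels(g, labels)
            acc = np.mean([res.labels[m] == "B" for m in masked])
            assert acc >= 0.95

    def test_isolated_unknown_stays_unknown(self):
        g, truth = generate_sbm_graph(PlantedSpec(100, [50, 50], 0.3, 0.03, seed=0))
        g2 = CellGraph(105, g.edges)  # nodes 100..104 isolated
        labels = ["A" if t == 0 else "B" for t in truth] + ["Unknown"] * 5
        res = transfer_labels(g2, labels)
        assert res.labels[100:] == ["Unknown"] * 5

    def test_annotated_cells_never_change(self):
        g, truth = generate_sbm_graph(PlantedSpec(100, [50, 50], 0.3, 0.03, seed=1))
        labels = ["A" if t == 0 else "B" for t in truth]
        labels[10] = "Unknown"
        res = transfer_labels(g, labels)
        for i in range(100):
            if i != 10:
                assert res.labels[i] == labels[i]
        # ranking covers every label present at the fixed point, best first
        assert res.ranking.shape == (100, len(res.affinity.columns))
        top = res.ranking[:, 0]
        assert [res.affinity.columns[t] for t in top] == res.affinity.argmax_labels()


class TestRmtKhat:
    def test_null_noise_finds_nothing(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = ExpressionMatrix(
                np.abs(rng.normal(3.0, 1.0, size=(300, 150))),
                [f"c{i}" for i in range(300)],
                [f"g{j}" for j in range(150)],
                layer="lognorm",
            )
            hits += rmt_khat(X) <= 1
        assert hits >= 9

    def test_four_groups_give_k_near_four(self):
        for seed in range(3):
            groups = np.repeat(np.arange(4), 75)
            X = normalize_log(generate_expression(groups, 400, 5.0, seed=seed))
            assert 3 <= rmt_khat(X) <= 5

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(2.0, 1.0, size=(100, 60))
        X = ExpressionMatrix(vals, [f"c{i}" for i in range(100)],
                             [f"g{j}" for j in range(60)], layer="lognorm")
        perm = rng.permutation(60)
        Xp = ExpressionMatrix(vals[:, perm], X.cell_ids,
                              [X.gene_ids[j] for j in perm], layer="lognorm")
        assert rmt_khat(X) == rmt_khat(Xp)

    def test_constant_genes_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(50, 10))
        vals[:, 0] = 1.0
        X = ExpressionMatrix(vals, [f"c{i}" for i in range(50)],
                             [f"g{j}" for j in range(10)], layer="lognorm")
        with pytest.warns(UserWarning, match="constant genes"):
            rmt_khat(X)


class TestLevelSelection:
    def test_argmin_examples(self):
        assert select_level_k(LevelStats(B=[12, 5, 2, 1], Q=[], k_hat=6)) == 1
        assert select_level_k(LevelStats(B=[8, 4, 2, 1], Q=[], k_hat=4)) == 1
        # tie |4-3| == |2-3| resolved toward the coarser level
        assert select_level_k(LevelStats(B=[8, 4, 2, 1], Q=[], k_hat=3)) == 2

    def test_modularity_two_triangles(self, two_triangles):
        part = NestedPartition.from_flat(np.array([0, 0, 0, 1, 1, 1]))
        level, Q = select_level_q(two_triangles, part)
        assert level == 0
        assert np.isclose(Q[0], 0.5)
        assert np.isclose(Q[1], 0.0)  # single block

    def test_modularity_relabel_invariant(self, two_triangles):
        b = np.array([0, 0, 0, 1, 1, 1])
        assert np.isclose(
            modularity(two_triangles, b), modularity(two_triangles, 1 - b)
        )

    def test_modularity_matches_networkx(self):
        import networkx as nx

        g, truth = generate_sbm_graph(PlantedSpec(80, [40, 40], 0.3, 0.05, seed=0))
        gx = nx.Graph(list(map(tuple, g.edges)))
        gx.add_nodes_from(range(80))
        comms = [set(np.flatnonzero(truth == r)) for r in range(2)]
        assert np.isclose(
            modularity(g, truth),
            nx.algorithms.community.modularity(gx, comms),
        )

    def test_compute_level_stats_full(self, two_triangles):
        part = NestedPartition.from_flat(np.array([0, 0, 0, 1, 1, 1]))
        stats = compute_level_stats(two_triangles, part, k_hat=2)
        assert stats.B == [2, 1]
        assert stats.i_k == 0 and stats.i_q == 0


class TestMetrics:
    def test_ari_examples(self):
        assert adjusted_rand_index([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert np.isclose(adjusted_rand_index([0, 0, 1, 1], [0, 1, 0, 1]), -0.5)
        a, b = [0, 1, 1, 2], [1, 1, 0, 2]
        assert adjusted_rand_index(a, b) == adjusted_rand_index(b, a)
        with pytest.raises(ValueError):
            adjusted_rand_index([0, 1], [0, 1, 1])

    def test_ks_identical_graphs(self, two_triangles):
        D, p = ks_degree_test(two_triangles, two_triangles)
        assert D == 0.0 and p == 1.0

    def test_ks_regular_vs_star(self):
        n = 50
        ring = CellGraph(n, np.array([(i, (i + 1) % n) for i in range(n)]))
        star = CellGraph(n, np.array([(0, i) for i in range(1, n)]))
        D, p = ks_degree_test(ring, star)
        assert p < 0.01
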