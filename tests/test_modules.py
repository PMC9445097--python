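import networkx as nx
import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from skullnet import (
    topological_overlap,
    ward_d2,
    modularity_q,
    cut_max_q,
    s_module_test,
    detect_modules,
    Partition,
    SkullSimConfig,
    simulate_skull,
)
from skullnet.network import mirror_label
from conftest import net_from_adjacency, net_from_edges
from oracles import brute_force_max_modularity, random_connected_adjacency


def two_triangles():
    return net_from_edges(
        [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
    )


class TestTopologicalOverlap:
    def test_triangle_edges_fully_overlap(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        t = topological_overlap(net).values
        assert np.allclose(t, 1.0)

    def test_isolated_dyad_overlap_one(self):
        net = net_from_edges([("a", "b")])
        t = topological_overlap(net).values
        assert t[0, 1] == pytest.approx(1.0)

    def test_no_shared_structure_is_zero(self):
        # endpoints of a path of length 3 share nothing at m=1
        net = net_from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        om = topological_overlap(net)
        i, j = om.labels.index("a"), om.labels.index("d")
        assert om.values[i, j] == 0.0

    def test_path_endpoints_share_middle(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        om = topological_overlap(net)
        i, j = om.labels.index("a"), om.labels.index("c")
        # one shared neighbor, no direct edge: (1+0)/(1+1-0)
        assert om.values[i, j] == pytest.approx(0.5)

    def test_matrix_contract(self, rng):
        adj = random_connected_adjacency(rng, 15)
        om = topological_overlap(net_from_adjacency(adj))
        v = om.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert (v >= 0).all() and (v <= 1).all()

    def test_identical_closed_neighborhoods_overlap_one(self):
        # a and b adjacent, both connected to c and d: closed nbhds coincide
        net = net_from_edges([("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")])
        om = topological_overlap(net)
        i, j = om.labels.index("a"), om.labels.index("b")
        assert om.values[i, j] == pytest.approx(1.0)

    def test_higher_order_saturates_small_graph(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        om = topological_overlap(net, m=3)  # everything within 3 steps
        assert np.allclose(om.values, 1.0)

    def test_invalid_order_rejected(self, toy_net):
        with pytest.raises(ValueError):
            topological_overlap(toy_net, m=0)


class TestWardD2:
    def test_matches_scipy_on_random_dissimilarities(self, rng):
        for _ in range(10):
            pts = rng.random((8, 4))
            d = squareform(pdist(pts))
            mine = sorted(h for _, _, h, _ in ward_d2(d).merges)
            ref = sorted(linkage(squareform(d), method="ward")[:, 2])
            assert np.allclose(mine, ref, atol=1e-9)

    def test_two_identical_pairs_merge_at_zero(self):
        pts = np.array([[0.0, 0], [0, 0], [10, 0], [10, 0]])
        d = squareform(pdist(pts))
        dend = ward_d2(d, labels=["a", "b", "c", "d"])
        heights = [h for _, _, h, _ in dend.merges]
        assert heights[0] == 0.0 and heights[1] == 0.0
        assert heights[2] > 0

    def test_monotone_heights(self, rng):
        d = squareform(pdist(rng.random((12, 3))))
        heights = [h for _, _, h, _ in ward_d2(d).merges]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_all_equal_dissimilarities_tiebreak_lexicographic(self):
        d = np.ones((4, 4)) - np.eye(4)
        dend = ward_d2(d, labels=["b", "a", "d", "c"])
        first_a, first_b, _, _ = dend.merges[0]
        merged = {dend.labels[first_a], dend.labels[first_b]}
        assert merged == {"a", "b"}

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            ward_d2(bad)

    def test_cut_produces_contiguous_modules(self, rng):
        d = squareform(pdist(rng.random((9, 2))))
        dend = ward_d2(d)
        for k in range(1, 10):
            part = dend.cut(k)
            assert part.k == k


class TestModularity:
    def test_single_module_is_zero(self, toy_net):
        part = Partition({l: 1 for l in toy_net.labels})
        assert modularity_q(toy_net, part) == pytest.approx(0.0, abs=1e-15)

    def test_two_triangles_natural_split(self):
        net = two_triangles()
        part = Partition({"a": 1, "b": 1, "c": 1, "x": 2, "y": 2, "z": 2})
        assert modularity_q(net, part) == pytest.approx(0.5)

    def test_breaking_a_triangle_loses_quality(self):
        net = two_triangles()
        worse = Partition({"a": 1, "b": 1, "c": 2, "x": 3, "y": 3, "z": 3})
        assert modularity_q(net, worse) < 0.5

    def test_agrees_with_networkx(self, rng):
        for _ in range(5):
            adj = random_connected_adjacency(rng, 12)
            net = net_from_adjacency(adj)
            labels = net.labels
            ids = rng.integers(1, 4, size=12)
            ids = np.unique(ids, return_inverse=True)[1] + 1  # contiguous
            part = Partition(dict(zip(labels, (int(i) for i in ids))))
            communities = [set(part.members(s)) for s in range(1, part.k + 1)]
            ref = nx.community.modularity(net.to_networkx(), communities)
            assert modularity_q(net, part) == pytest.approx(ref, abs=1e-12)

    def test_missing_node_rejected(self, toy_net):
        part = Partition({l: 1 for l in toy_net.labels[:-1]})
        with pytest.raises(ValueError, match="missing"):
            modularity_q(toy_net, part)


class TestCutMaxQ:
    def test_two_triangles_recovered(self):
        net = two_triangles()
        report = detect_modules(net)
        assert report.q_modules == 2
        assert report.q_max == pytest.approx(0.5)
        mods = {frozenset(report.partition.members(s)) for s in (1, 2)}
        assert mods == {frozenset("abc"), frozenset("xyz")}

    def test_complete_graph_stays_whole(self):
        net = net_from_adjacency(nx.to_numpy_array(nx.complete_graph(6), dtype=int))
        report = detect_modules(net)
        assert report.q_modules == 1 and report.q_max == pytest.approx(0.0, abs=1e-15)

    def test_planted_two_block_recovered(self):
        rng = np.random.default_rng(7)
        sizes = [8, 8]
        p = [[0.8, 0.05], [0.05, 0.8]]
        g = nx.stochastic_block_model(sizes, p, seed=11)
        while not nx.is_connected(g):
            g = nx.stochastic_block_model(sizes, p, seed=int(rng.integers(1 << 30)))
        net = net_from_adjacency(nx.to_numpy_array(g, dtype=int))
        report = detect_modules(net)
        truth = [0] * 8 + [1] * 8
        found = [report.partition.assignment[l] for l in net.labels]
        assert adjusted_rand_score(truth, found) == pytest.approx(1.0)

    def test_returned_cut_beats_every_other_cut(self, rng):
        adj = random_connected_adjacency(rng, 10)
        net = net_from_adjacency(adj)
        om = topological_overlap(net)
        dend = ward_d2(om.dissimilarity(), labels=om.labels)
        part, q_max = cut_max_q(net, dend)
        for k in range(1, 11):
            assert q_max >= modularity_q(net, dend.cut(k)) - 1e-12

    def test_dendrogram_cut_below_global_optimum(self, rng):
        """Dendrogram cuts search a subspace: Q_max <= brute-force max."""
        gaps = []
        for _ in range(5):
            n = int(rng.integers(5, 8))
            adj = random_connected_adjacency(rng, n)
            net = net_from_adjacency(adj)
            _, q_max = cut_max_q(
                net,
                ward_d2(topological_overlap(net).dissimilarity(),
                        labels=net.labels),
            )
            global_max = brute_force_max_modularity(adj)
            assert q_max <= global_max + 1e-12
            gaps.append(global_max - q_max)
        assert min(gaps) >= -1e-12  # gaps are nonnegative up to float error


class TestSModules:
    def test_disconnected_clique_is_significant(self):
        # module "abcd" is a clique with zero external contact
        net = net_from_edges(
            [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d"),
             ("x", "y")]
        )
        part = Partition({"a": 1, "b": 1, "c": 1, "d": 1, "x": 2, "y": 2})
        report = s_module_test(net, part)
        assert report.p_values[1] < 0.05
        assert report.s_modules >= 1

    def test_no_separation_not_significant(self):
        # ring of 4 modules: every node has 1 internal and 1 external contact
        net = net_from_edges(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "f"), ("f", "a")]
        )
        part = Partition({"a": 1, "b": 1, "c": 2, "d": 2, "e": 3, "f": 3})
        report = s_module_test(net, part)
        assert all(p >= 0.05 for p in report.p_values.values())
        assert report.s_modules == 0

    def test_singleton_module_skipped_with_warning(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        part = Partition({"a": 1, "b": 1, "c": 2})
        with pytest.warns(UserWarning, match="skipped"):
            report = s_module_test(net, part)
        assert report.p_values[2] == 1.0

    def test_counts_respect_alpha(self, toy_net):
        report = detect_modules(toy_net)
        assert report.s_modules == sum(
            1 for p in report.p_values.values() if p < report.alpha
        )
        assert report.s_modules <= report.q_modules


class TestPipelineProperties:
    def test_mirror_symmetric_partition(self, toy_net):
        report = detect_modules(toy_net)
        part = report.partition
        mirrored = part.relabeled(mirror_label)
        mods = lambda p: {frozenset(p.members(s)) for s in range(1, p.k + 1)}
        assert mods(part) == mods(mirrored)

    def test_planted_four_module_recovery(self):
        hits = []
        for seed in range(100):
            sim = simulate_skull(
                SkullSimConfig(
                    n_bone_pairs=14, n_midline_bones=2, n_modules_per_side=2,
                    p_within=0.8, p_between=0.05, p_cross_midline=0.02, seed=seed,
                )
            )
            report = detect_modules(sim.network)
            labels = sim.network.labels
            truth = [sim.planted.assignment[l] for l in labels]
            found = [report.partition.assignment[l] for l in labels]
            hits.append(adjusted_rand_score(truth, found) >= 0.9)
        assert np.mean(hits) >= 0.9

    def test_planted_two_module_recovery(self):
        hits = []
        for seed in range(50):
            sim = simulate_skull(
                SkullSimConfig(
                    n_bone_pairs=8, n_midline_bones=1, n_modules_per_side=1,
                    p_within=0.8, p_between=0.05, p_cross_midline=0.02, seed=seed,
                )
            )
            report = detect_modules(sim.network)
            labels = sim.network.labels
            truth = [sim.planted.assignment[l] for l in labels]
            found = [report.partition.assignment[l] for l in labels]
            hits.append(adjusted_rand_score(truth, found) >= 0.9)
        assert np.mean(hits) >= 0.9

    def test_newick_export_covers_all_leaves(self, toy_net):
        report = detect_modules(toy_net)
        nwk = report.dendrogram.to_newick()
        for label in toy_net.labels:
            assert label in nwk
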