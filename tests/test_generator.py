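"""Generation pipeline: motifs, growth, wiring, labels, features, ground truth."""

import numpy as np
import pytest

import shapeggen as sg
from shapeggen.generator import (
    add_redundant_and_protected,
    apply_homophily,
    assign_labels,
    connect_subgraphs,
    generate_informative_features,
    grow_subgraph,
)
from shapeggen.model import canonical_edge


class TestMakeMotif:
    def test_house(self):
        m = sg.make_motif("house")
        assert len(m.node_ids) == 5
        assert len(m.edge_set) == 6

    def test_triangle(self):
        m = sg.make_motif("triangle")
        assert len(m.node_ids) == 3
        assert len(m.edge_set) == 3

    def test_custom_template_passthrough(self):
        custom = sg.MotifInstance("custom", (0, 1), frozenset({(0, 1)}))
        assert sg.make_motif(custom) is custom

    def test_unknown_shape_raises(self):
        with pytest.raises(ValueError, match="house"):
            sg.make_motif("pentagon")


class TestGrowSubgraph:
    def test_lambda_zero_returns_bare_motif(self, rng):
        motif = sg.make_motif("house")
        local = grow_subgraph(motif, 5, 1, rng)
        assert local.num_nodes == 5
        assert set(local.edges) == set(canonical_edge(*e) for e in motif.edge_set)

    def test_single_attachment_edge_count(self, rng):
        motif = sg.make_motif("house")
        for _ in range(10):
            local = grow_subgraph(motif, 12, 1, rng)
            n_extra = local.num_nodes - 5
            assert len(local.edges) == 6 + n_extra

    def test_mean_size_matches_expectation(self):
        motif = sg.make_motif("triangle")
        rng = np.random.default_rng(11)
        sizes = [grow_subgraph(motif, 9, 1, rng).num_nodes for _ in range(400)]
        assert np.mean(sizes) == pytest.approx(9, rel=0.05)

    def test_motif_smaller_than_target_required(self, rng):
        with pytest.raises(ValueError):
            grow_subgraph(sg.make_motif("house"), 3, 1, rng)


class TestConnectSubgraphs:
    def test_p_zero_no_bridges_all_class_zero(self, rng):
        motif = sg.make_motif("house")
        subs = [grow_subgraph(motif, 8, 1, rng) for _ in range(5)]
        g = connect_subgraphs(subs, 0.0, 2, rng)
        assert len(g.undirected_edges) == sum(len(s.edges) for s in subs)
        labels = assign_labels(g, 2)
        assert np.all(labels == 0)

    def test_two_bare_motifs_p_one(self, rng):
        # bare houses: both ordered pairs fire -> two bridges between the
        # motifs, and every bridge endpoint sees both motifs
        motif = sg.make_motif("house")
        subs = [grow_subgraph(motif, 5, 1, rng) for _ in range(2)]
        g = connect_subgraphs(subs, 1.0, 2, rng)
        assert len(g.undirected_edges) == 12 + 2
        bridge_ends = {
            u for u, v in g.undirected_edges
            if (u < 5) != (v < 5) for u in (u, v)
        }
        for u in bridge_ends:
            assert sg.motif_count(g, u) == 2
        counts = [sg.motif_count(g, v) for v in range(g.num_nodes)]
        assert set(counts) <= {1, 2}

    def test_needs_two_subgraphs(self, rng):
        with pytest.raises(ValueError):
            connect_subgraphs([grow_subgraph(sg.make_motif("house"), 5, 1, rng)],
                              0.5, 2, rng)


class TestLabels:
    def test_label_is_clipped_count_minus_one(self, tiny_ds):
        g = tiny_ds.graph
        K = tiny_ds.config.num_classes
        for v in range(g.num_nodes):
            closed = set(map(int, g.neighbors(v))) | {v}
            count = sum(1 for m in g.motifs if closed & set(m.node_ids))
            assert g.labels[v] == min(max(count - 1, 0), K - 1)

    def test_both_classes_present(self, small_ds):
        assert set(np.unique(small_ds.graph.labels)) == {0, 1}


class TestInformativeFeatures:
    def test_class_separation_improves_linear_accuracy(self):
        from sklearn.linear_model import LogisticRegression

        labels = np.random.default_rng(1).integers(0, 2, 3000)
        accs = []
        for s_f in (0.3, 0.6, 1.5):
            X = generate_informative_features(
                labels, 4, s_f, 2, 2, np.random.default_rng(2)
            )
            clf = LogisticRegression().fit(X[:2000], labels[:2000])
            accs.append(clf.score(X[2000:], labels[2000:]))
        assert accs[0] < accs[1] < accs[2]

    def test_zero_separation_collapses_class_means(self):
        labels = np.random.default_rng(1).integers(0, 2, 4000)
        X = generate_informative_features(labels, 4, 0.0, 2, 2,
                                          np.random.default_rng(2))
        gap = np.abs(X[labels == 0].mean(0) - X[labels == 1].mean(0))
        assert np.all(gap < 0.15)  # noise-level difference only

    def test_uses_requested_number_of_centroids(self):
        # with no noise the features sit exactly on the centroids
        labels = np.repeat([0, 1], 200)
        rng = np.random.default_rng(3)
        X = generate_informative_features(labels, 4, 1.0, 2, 2, rng)
        # subtracting the Gaussian noise is impossible post hoc; instead check
        # the rounded sign patterns: 2 classes x 2 clusters = 4 distinct cells
        patterns = {tuple(np.sign(row).astype(int)) for row in X}
        assert len(patterns) >= 4

    def test_too_few_hypercube_vertices(self):
        with pytest.raises(ValueError):
            generate_informative_features(np.zeros(5, int), 1, 1.0, 2, 2,
                                          np.random.default_rng(0))


class TestProtectedFeature:
    @pytest.mark.parametrize("phi,expected_r", [(0.0, 1.0), (0.25, 0.5),
                                                (0.5, 0.0), (0.75, -0.5),
                                                (1.0, -1.0)])
    def test_phi_controls_label_correlation(self, sg_base, phi, expected_r):
        g = sg_base.graph
        X, _, prot = add_redundant_and_protected(
            g.features[:, :4], g.labels, 11, 4, phi, np.random.default_rng(42)
        )
        r = np.corrcoef((g.labels > 0).astype(float), X[:, prot])[0, 1]
        assert r == pytest.approx(expected_r, abs=0.05)

    def test_layout(self, sg_base):
        g = sg_base.graph
        assert g.informative_feature_indices == (0, 1, 2, 3)
        assert g.protected_feature_index == 10
        assert set(np.unique(g.features[:, 10])) <= {0.0, 1.0}


class TestHomophily:
    def test_eta_zero_only_rescales(self, tiny_ds):
        g = tiny_ds.graph
        red = tuple(range(4, 10))
        X0 = np.random.default_rng(0).standard_normal((g.num_nodes, 11))
        X = apply_homophily(g, X0, 0.0, red)
        R0, R = X0[:, list(red)], X[:, list(red)]
        cos = (R0 * R).sum(1) / (np.linalg.norm(R0, axis=1) * np.linalg.norm(R, axis=1))
        assert np.allclose(cos, 1.0)

    def test_symmetric_pair_stays_identical(self):
        g = sg.SyntheticGraph(2, [(0, 1)])
        X = np.tile(np.array([[1.0, 2.0, 3.0]]), (2, 1))
        out = apply_homophily(g, X, 1.0, (0, 1, 2))
        assert np.allclose(out[0], out[1])

    def test_sign_of_eta_controls_neighbor_cosine(self, small_ds):
        g = small_ds.graph
        red = tuple(range(4, 10))
        E = np.array(g.undirected_edges)

        def neighbor_cos(X):
            a, b = X[E[:, 0]], X[E[:, 1]]
            return np.mean(
                (a * b).sum(1)
                / (np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
            )

        Xp = apply_homophily(g, g.features, +1.0, red)
        Xm = apply_homophily(g, g.features, -1.0, red)
        assert neighbor_cos(Xp) > neighbor_cos(Xm)

    def test_untouched_channels(self, tiny_ds):
        g = tiny_ds.graph
        X0 = np.random.default_rng(0).standard_normal((g.num_nodes, 11))
        X = apply_homophily(g, X0, 1.0, (4, 5, 6, 7, 8, 9))
        assert np.array_equal(X[:, :4], X0[:, :4])
        assert np.array_equal(X[:, 10], X0[:, 10])


class TestGroundTruth:
    def test_masks_match_naive_set_computation(self, tiny_ds):
        g = tiny_ds.graph
        L = tiny_ds.config.gnn_layers
        for v in range(0, g.num_nodes, 3):
            sub = sg.enclosing_subgraph(g, v, L)
            in_sub = set(map(int, sub.node_ids))
            hit = [m for m in g.motifs if set(m.node_ids) & in_sub]
            gts = tiny_ds.ground_truth[v]
            assert len(gts) == max(len(hit), 1)
            for mask, motif in zip(gts, hit):
                mset = set(motif.node_ids) & in_sub
                expect_nodes = [1.0 if int(u) in mset else 0.0
                                for u in sub.node_ids]
                assert mask.node_scores.tolist() == expect_nodes
                keep = mset | {v}
                expect_edges = [1.0 if (a in keep and b in keep) else 0.0
                                for a, b in sub.edges]
                assert mask.edge_scores.tolist() == expect_edges

    def test_feature_mask_marks_informative_columns(self, sg_base):
        gts = sg_base.ground_truth[0]
        fm = gts.masks[0].feature_scores
        assert fm.sum() == 4
        assert np.all(fm[:4] == 1)
        assert fm[10] == 0  # protected column excluded

    def test_node_mask_sums_to_motif_overlap(self, tiny_ds):
        g = tiny_ds.graph
        v = int(g.motifs[0].node_ids[0])
        sub = sg.enclosing_subgraph(g, v, 3)
        in_sub = set(map(int, sub.node_ids))
        for mask, motif in zip(
            tiny_ds.ground_truth[v],
            [m for m in g.motifs if set(m.node_ids) & in_sub],
        ):
            assert mask.node_scores.sum() == len(set(motif.node_ids) & in_sub)

    def test_edge_between_nonmotif_nodes_is_zero(self, tiny_ds):
        g = tiny_ds.graph
        motif_nodes = {u for m in g.motifs for u in m.node_ids}
        found = False
        for v in range(g.num_nodes):
            sub = sg.enclosing_subgraph(g, v, 3)
            for mask in tiny_ds.ground_truth[v]:
                for (a, b), val in zip(sub.edges, mask.edge_scores):
                    if a not in motif_nodes and b not in motif_nodes \
                            and a != v and b != v:
                        assert val == 0.0
                        found = True
            if found:
                break
        assert found


class TestGenerate:
    def test_node_count_near_expectation(self, sg_base):
        cfg = sg_base.config
        expect = cfg.num_subgraphs * cfg.subgraph_size
        sd = np.sqrt(cfg.num_subgraphs * (cfg.subgraph_size - 5))
        assert abs(sg_base.graph.num_nodes - expect) < 3 * sd

    def test_mean_node_count_over_seeds(self):
        cfg = sg.preset("SG-Base").replace(num_subgraphs=100)
        sizes = [
            sg.generate(cfg.replace(seed=s)).graph.num_nodes for s in range(20)
        ]
        assert np.mean(sizes) == pytest.approx(100 * 11, rel=0.01)

    def test_seed_determinism(self):
        cfg = sg.preset("SG-Base").replace(num_subgraphs=40, seed=9)
        a, b = sg.generate(cfg), sg.generate(cfg)
        assert a.graph.undirected_edges == b.graph.undirected_edges
        assert np.array_equal(a.graph.features, b.graph.features)
        assert np.array_equal(a.split, b.split)
        m1 = a.ground_truth[0].masks[0]
        m2 = b.ground_truth[0].masks[0]
        assert np.array_equal(m1.node_scores, m2.node_scores)
        assert np.array_equal(m1.edge_scores, m2.edge_scores)

    def test_split_fractions(self, sg_base):
        n = sg_base.graph.num_nodes
        assert len(sg_base.train_nodes) == pytest.approx(0.70 * n, abs=3)
        assert len(sg_base.val_nodes) == pytest.approx(0.05 * n, abs=3)
        assert len(sg_base.test_nodes) == pytest.approx(0.25 * n, abs=3)

    def test_every_node_has_ground_truth(self, tiny_ds):
        assert len(tiny_ds.ground_truth) == tiny_ds.graph.num_nodes
        assert all(len(tiny_ds.ground_truth[v]) >= 1
                   for v in range(tiny_ds.graph.num_nodes))


class TestPresets:
    def test_base_parameters(self):
        c = sg.preset("SG-Base")
        assert (c.motif_shape, c.num_subgraphs, c.connection_prob,
                c.subgraph_size, c.num_classes, c.num_features,
                c.num_informative, c.class_sep, c.clusters_per_class,
                c.protected_noise, c.homophily, c.gnn_layers) == (
            "house", 1200, 0.006, 11, 2, 11, 4, 0.6, 2, 0.5, 1, 3)

    def test_variants(self):
        assert sg.preset("SG-Unfair").protected_noise == 0.75
        assert sg.preset("SG-Heterophilic").homophily == -1
        assert sg.preset("SG-MoreInform").num_informative == 8
        assert sg.preset("SG-MoreInform").num_features == 11
        assert sg.preset("SG-LessInform").num_features == 21
        assert sg.preset("SG-LessInform").num_informative == 4
        small = sg.preset("SG-SmallEx")
        assert small.motif_shape == "triangle"
        assert (small.num_subgraphs, small.subgraph_size, small.class_sep) == \
            (1300, 12, 0.5)

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="SG-Base"):
            sg.preset("SG-Bogus")


class TestBAShapes:
    def test_no_houses_all_label_zero(self):
        ds = sg.ba_shapes(30, 0, seed=1)
        assert np.all(ds.graph.labels == 0)

    def test_node_count(self):
        ds = sg.ba_shapes(50, 4, perturb_edges=3, seed=1)
        assert ds.graph.num_nodes == 50 + 5 * 4

    def test_house_nodes_labeled_one(self):
        ds = sg.ba_shapes(40, 3, seed=2)
        for m in ds.graph.motifs:
            assert np.all(ds.graph.labels[list(m.node_ids)] == 1)
        assert np.all(ds.graph.labels[:40] == 0)


class TestConfigIO:
    def test_flat_roundtrip(self, tmp_path):
        cfg = sg.preset("SG-SmallEx").replace(seed=5)
        p = tmp_path / "cfg.json"
        cfg.to_json(p)
        assert sg.GeneratorConfig.from_json(p) == cfg

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            sg.GeneratorConfig(num_informative=11, num_features=11)
        with pytest.raises(ValueError):
            sg.GeneratorConfig(num_classes=1)
        with pytest.raises(ValueError):
            sg.GeneratorConfig(subgraph_size=3)  # smaller than house
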