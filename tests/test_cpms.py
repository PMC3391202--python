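import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import chronomorph as cm
from chronomorph.tree import TreeError

from conftest import random_binary_tree


def two_tip_tree(v1=1.0, v2=1.0):
    t = cm.read_newick(f"(A:{v1},B:{v2});")
    # date directly so unequal terminal branches are allowed
    t.root.age = max(v1, v2)
    t.find_tip("A").age = t.root.age - v1
    t.find_tip("B").age = t.root.age - v2
    return t


class TestAncestralMl:
    def test_symmetric_root(self):
        t = two_tip_tree(1, 1)
        st = cm.ancestral_ml(t, pd.Series({"A": 0.0, "B": 4.0}, name="x"))
        assert st.estimates.loc["node0", "x"] == pytest.approx(2.0)

    def test_precision_weighted_root(self):
        t = two_tip_tree(1, 3)
        st = cm.ancestral_ml(t, pd.Series({"A": 0.0, "B": 4.0}, name="x"))
        assert st.estimates.loc["node0", "x"] == pytest.approx(1.0)

    def test_tips_are_observed_with_zero_variance(self):
        t = two_tip_tree()
        st = cm.ancestral_ml(t, pd.Series({"A": 0.0, "B": 4.0}, name="x"))
        assert st.estimates.loc["A", "x"] == 0.0
        assert st.variances.loc["A", "x"] == 0.0

    def test_matches_numerical_minimization(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            t = random_binary_tree(rng, 12)
            tips = t.tip_labels()
            x = pd.Series(rng.normal(size=12), index=tips, name="x")
            st = cm.ancestral_ml(t, x)
            internal = t.internal_nodes()

            def objective(vals):
                node_val = {id(nd): v for nd, v in zip(internal, vals)}
                for tip in t.tips():
                    node_val[id(tip)] = x[tip.label]
                s = 0.0
                for node in t.preorder():
                    if node.parent is None:
                        continue
                    dx = node_val[id(node)] - node_val[id(node.parent)]
                    s += dx * dx / node.duration
                return s

            x0 = np.full(len(internal), x.mean())
            opt = minimize(objective, x0, method="BFGS",
                           options={"gtol": 1e-12})
            from chronomorph.cpms import _node_ids
            ids = _node_ids(t)
            mine = np.array([st.estimates.loc[ids[id(nd)], "x"]
                             for nd in internal])
            np.testing.assert_allclose(mine, opt.x, atol=1e-6)

    def test_root_equals_gls_phylogenetic_mean(self):
        rng = np.random.default_rng(1)
        t = random_binary_tree(rng, 20)
        tips = t.tip_labels()
        x = pd.Series(rng.normal(size=20), index=tips, name="x")
        st = cm.ancestral_ml(t, x)
        V = t.shared_path_matrix(labels=tips).to_numpy()
        Vinv = np.linalg.inv(V)
        one = np.ones(20)
        gls = one @ Vinv @ x.loc[tips].to_numpy() / (one @ Vinv @ one)
        assert st.estimates.loc["node0", "x"] == pytest.approx(gls, rel=1e-9)

    def test_reml_rate_is_contrast_mean_square(self):
        rng = np.random.default_rng(2)
        t = random_binary_tree(rng, 10)
        x = pd.Series(rng.normal(size=10), index=t.tip_labels(), name="x")
        st = cm.ancestral_ml(t, x, method="reml")
        contrasts = cm.pic(t, x)["contrast"]
        assert st.rate[0] == pytest.approx((contrasts ** 2).mean())

    def test_zero_duration_edge_rejected(self):
        t = cm.read_newick("((A:0,B:1):1,C:2);")
        t.assign_ages_from_lengths()
        with pytest.raises(TreeError):
            cm.ancestral_ml(t, pd.Series({"A": 1.0, "B": 2.0, "C": 3.0}))


class TestPhylomorphospace:
    def scores_for(self, tree, rng):
        return pd.DataFrame(
            rng.normal(size=(len(tree.tips()), 2)),
            index=tree.tip_labels(), columns=["PC1", "PC2"],
        )

    def test_two_tip_root_at_weighted_mean(self):
        t = two_tip_tree(1, 3)
        scores = pd.DataFrame({"PC1": [0.0, 4.0], "PC2": [0.0, 4.0]},
                              index=["A", "B"])
        g = cm.build_phylomorphospace(t, scores)
        assert g.nodes.loc["node0", "PC1"] == pytest.approx(1.0)

    def test_edge_count_binary(self):
        rng = np.random.default_rng(3)
        t = random_binary_tree(rng, 25)
        g = cm.build_phylomorphospace(t, self.scores_for(t, rng))
        assert len(g.edges) == 2 * 25 - 2
        assert len(g.nodes) == 2 * 25 - 1

    def test_root_ci_coverage(self):
        # ~95% of BM replicates put the true root inside the reported CI
        hits = 0
        n_rep = 400
        cfg0 = cm.SimConfig(seed=0, n_tips=40, n_traits=2,
                            fossil_fraction=0.0, bm_sigma2=0.3)
        tree, _ = cm.sim_birth_tree(cfg0)
        for seed in range(n_rep):
            cfg = cm.SimConfig(seed=seed, n_tips=40, n_traits=2,
                               fossil_fraction=0.0, bm_sigma2=0.3)
            traits = cm.sim_bm_traits(tree, cfg)
            st = cm.ancestral_ml(tree, traits[["trait1"]])
            ci = st.ci("trait1").loc["node0"]
            hits += ci.lower <= cfg.root_state <= ci.upper
        assert hits / n_rep == pytest.approx(0.95, abs=0.025)


class TestCpms:
    def test_z_equals_tree_ages(self, scaled_tree, morphospace):
        cents = morphospace["centroids"].loc[scaled_tree.tip_labels()]
        g = cm.build_cpms(scaled_tree, cents[["PC1", "PC2"]])
        for tip in scaled_tree.tips():
            assert g.nodes.loc[tip.label, "age"] == tip.age
        for parent, child in g.edges:
            assert g.nodes.loc[parent, "age"] >= g.nodes.loc[child, "age"]

    def test_projection_identity_bit_exact(self, scaled_tree, morphospace):
        cents = morphospace["centroids"].loc[scaled_tree.tip_labels()]
        g3 = cm.build_cpms(scaled_tree, cents[["PC1", "PC2"]])
        g2 = cm.build_phylomorphospace(scaled_tree, cents[["PC1", "PC2"]])
        assert (g3.projection_2d().to_numpy() ==
                g2.projection_2d().to_numpy()).all()

    def test_extant_only_tree_tips_at_zero(self):
        cfg = cm.SimConfig(seed=5, n_tips=10, n_traits=2, fossil_fraction=0.0)
        tree, _ = cm.sim_birth_tree(cfg)
        scores = cm.sim_bm_traits(tree, cfg)
        scores.columns = ["PC1", "PC2"]
        g = cm.build_cpms(tree, scores)
        tips = g.nodes[g.nodes.is_tip]
        np.testing.assert_allclose(tips["age"], 0.0, atol=1e-9)
        assert g.nodes["age"].max() == pytest.approx(tree.root.age)

    def test_unscaled_tree_rejected(self):
        t = cm.read_newick("((A:1,B:1):1,C:2);")
        scores = pd.DataFrame(np.zeros((3, 2)) + [[0, 0], [1, 1], [2, 2]],
                              index=["A", "B", "C"], columns=["PC1", "PC2"])
        with pytest.raises(TreeError):
            cm.build_cpms(t, scores)

    def test_invariant_under_tip_reordering(self, scaled_tree, morphospace):
        cents = morphospace["centroids"]
        sc = cents[["PC1", "PC2"]]
        g1 = cm.build_cpms(scaled_tree, sc)
        g2 = cm.build_cpms(scaled_tree, sc.iloc[::-1])
        assert (g1.nodes.to_numpy() == g2.nodes.to_numpy()).all()
        assert g1.edges == g2.edges


class TestCpms1d:
    def test_constant_trait_vertical_line(self):
        cfg = cm.SimConfig(seed=6, n_tips=8, n_traits=1, fossil_fraction=0.0)
        tree, _ = cm.sim_birth_tree(cfg)
        x = pd.Series(1.5, index=tree.tip_labels(), name="PC1")
        g = cm.build_cpms_1d(tree, x)
        np.testing.assert_allclose(g.nodes["PC1"], 1.5, atol=1e-9)
        internal = g.nodes[~g.nodes.is_tip]
        np.testing.assert_allclose(
            (internal["ci_lower"] + internal["ci_upper"]) / 2, 1.5, atol=1e-9)

    def test_two_tip_root_coordinates(self):
        t = two_tip_tree(1, 3)
        x = pd.Series({"A": 0.0, "B": 4.0}, name="PC1")
        g = cm.build_cpms_1d(t, x)
        assert g.nodes.loc["node0", "PC1"] == pytest.approx(1.0)
        assert g.nodes.loc["node0", "age"] == pytest.approx(t.root.age)

    def test_ci_width_shrinks_with_more_tips(self):
        widths = []
        for n in (8, 16, 64):
            cfg = cm.SimConfig(seed=7, n_tips=n, n_traits=1,
                               fossil_fraction=0.0, bm_sigma2=0.3)
            tree, _ = cm.sim_birth_tree(cfg)
            x = cm.sim_bm_traits(tree, cfg)["trait1"]
            x.name = "PC1"
            g = cm.build_cpms_1d(tree, x)
            w = (g.nodes["ci_upper"] - g.nodes["ci_lower"])
            widths.append(w.loc["node0"] / np.sqrt(g.nodes["age"].max()))
        assert widths[0] > widths[2]


class TestExport:
    def graph(self, scaled_tree, morphospace):
        cents = morphospace["centroids"].loc[scaled_tree.tip_labels()]
        return cm.build_cpms(scaled_tree, cents[["PC1", "PC2"]])

    def test_json_roundtrip(self, tmp_path, scaled_tree, morphospace):
        g = self.graph(scaled_tree, morphospace)
        path = tmp_path / "graph.json"
        cm.export_graph(g, path, format="json")
        g2 = cm.load_graph_json(path)
        assert g2.trait_names == g.trait_names
        assert g2.edges == g.edges
        np.testing.assert_allclose(
            g2.nodes[g.trait_names + ["age"]].to_numpy(),
            g.nodes[g.trait_names + ["age"]].to_numpy())

    def test_csv_row_counts(self, tmp_path, scaled_tree, morphospace):
        g = self.graph(scaled_tree, morphospace)
        cm.export_graph(g, tmp_path / "graph.csv", format="csv")
        nodes = pd.read_csv(tmp_path / "graph_nodes.csv")
        edges = pd.read_csv(tmp_path / "graph_edges.csv")
        assert len(nodes) == len(g.nodes)
        assert len(edges) == len(g.nodes) - 1
        ages = nodes.set_index("id")["age"]
        for tip in scaled_tree.tips():
            assert ages[tip.label] == pytest.approx(tip.age)

    def test_static_plots_written(self, tmp_path, scaled_tree, morphospace):
        g = self.graph(scaled_tree, morphospace)
        cm.export_graph(g, tmp_path / "cpms.png", format="plot")
        assert (tmp_path / "cpms.png").stat().st_size > 0
        cents = morphospace["centroids"].loc[scaled_tree.tip_labels()]
        g1 = cm.build_cpms_1d(scaled_tree, cents["PC1"])
        cm.plot_cpms(g1, tmp_path / "cpms1d.png")
        assert (tmp_path / "cpms1d.png").stat().st_size > 0
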