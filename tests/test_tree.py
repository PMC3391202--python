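import io

import numpy as np
import pandas as pd
import pytest

import chronomorph as cm
from chronomorph.tree import CalibrationRow, CalibrationTable, TreeError

from conftest import random_binary_tree


class TestNewickIO:
    def test_parse_basic(self):
        t = cm.read_newick("((A:1,B:1):1,C:2);")
        assert len(t) == 5
        assert sorted(t.tip_labels()) == ["A", "B", "C"]
        t.assign_ages_from_lengths()
        assert t.root.age == 2.0
        assert all(tip.age == 0.0 for tip in t.tips())

    def test_parse_without_lengths(self):
        t = cm.read_newick("(A,B);")
        assert all(n.length is None for n in t.preorder())
        assert all(n.duration is None for n in t.tips())

    def test_roundtrip_preserves_topology_and_lengths(self):
        rng = np.random.default_rng(7)
        t = random_binary_tree(rng, 50)
        t2 = cm.read_newick(t.to_newick())
        t2.assign_ages_from_lengths()
        d1 = t.patristic_distances()
        d2 = t2.patristic_distances(labels=list(d1.index))
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-8)

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(cm.NewickParseError, match="A"):
            cm.read_newick("((A:1,A:1):1,C:2);")

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(cm.NewickParseError):
            cm.read_newick("((A:1,B:1:1,C:2);")

    def test_nexus_trees_block(self):
        text = (
            "#NEXUS\nbegin trees;\n"
            "tree one = ((A:1,B:1):1,C:2);\n"
            "tree two = ((A:2,C:2):1,B:3);\nend;\n"
        )
        trees = cm.read_nexus_trees(text)
        assert len(trees) == 2
        assert sorted(trees[0].tip_labels()) == ["A", "B", "C"]


class TestGraft:
    def host(self):
        return cm.read_newick("((A:1,FELINAE:1):1,(C:1,D:1):1);")

    def test_tip_counts_add(self):
        donor = cm.read_newick("((x:1,y:1):1,z:2);")
        out = cm.graft_subtree(self.host(), "FELINAE", donor)
        assert len(out.tips()) == 4 + 3 - 1
        assert "FELINAE" not in out.tip_labels()
        assert set("xyz") <= set(out.tip_labels())

    def test_single_tip_donor_is_relabeling(self):
        donor = cm.read_newick("(only);").copy()
        # a 1-tip "tree": use the root-as-leaf form
        from chronomorph.tree import TimeTree, TreeNode
        donor = TimeTree(TreeNode("only"))
        out = cm.graft_subtree(self.host(), "FELINAE", donor)
        assert sorted(out.tip_labels()) == ["A", "C", "D", "only"]
        assert len(out) == len(self.host())

    def test_graft_then_prune_recovers_host(self):
        donor = cm.read_newick("((x:1,y:1):1,z:2);")
        out = cm.graft_subtree(self.host(), "FELINAE", donor)
        back = cm.prune(out, ["A", "C", "D"])
        assert sorted(back.tip_labels()) == ["A", "C", "D"]

    def test_errors(self):
        donor = cm.read_newick("(x:1,y:1);")
        with pytest.raises(TreeError):
            cm.graft_subtree(self.host(), "nope", donor)
        h = self.host()
        h.internal_nodes()[1].label = "inner"
        with pytest.raises(TreeError, match="internal"):
            cm.graft_subtree(h, "inner", donor)


def simple_calibration(**extra):
    rows = {
        "F1": CalibrationRow("F1", fo_ma=1.81, lo_ma=0.0117),
        "F2": CalibrationRow("F2", fo_ma=8.0, lo_ma=6.0),
        "E1": CalibrationRow("E1", fo_ma=3.8, lo_ma=0.0),
        "E2": CalibrationRow("E2", fo_ma=1.0, lo_ma=0.0),
    }
    return CalibrationTable(rows=rows, node_dates=list(extra.get("node_dates", [])))


class TestTimeScale:
    def tree(self):
        return cm.read_newick("((F1:1,E1:1):1,(F2:1,E2:1):1);")

    def test_fossil_midpoint_dating(self):
        cal = simple_calibration(node_dates=[CalibrationRow(
            "r", 30, 30, mrca_of="F1|F2", node_date_ma=30.0)])
        scaled = cm.time_scale(self.tree(), cal, mode="main")
        ages = {t.label: t.age for t in scaled.tips()}
        assert ages["F1"] == pytest.approx(0.91085)  # midpoint of 1.81-0.0117
        assert ages["F2"] == pytest.approx(7.0)

    def test_extant_extension(self):
        cal = simple_calibration(node_dates=[CalibrationRow(
            "r", 30, 30, mrca_of="F1|F2", node_date_ma=30.0)])
        on = cm.time_scale(self.tree(), cal, mode="main", extend_extant=True)
        off = cm.time_scale(self.tree(), cal, mode="main", extend_extant=False)
        assert {t.label: t.age for t in on.tips()}["E1"] == 0.0
        assert {t.label: t.age for t in off.tips()}["E1"] == pytest.approx(3.8)
        # first occurrence still constrains the parent even when extended
        parent = on.find_tip("E1").parent
        assert parent.age >= 3.8

    def test_molecular_vs_fossil_max_rule(self):
        # molecular date 10 at the F2/E2 node loses to fossil constraint 12
        rows = dict(simple_calibration().rows)
        rows["F2"] = CalibrationRow("F2", fo_ma=13.0, lo_ma=11.0)  # midpoint 12
        cal = CalibrationTable(rows=rows, node_dates=[
            CalibrationRow("a", 10, 10, mrca_of="F2|E2", node_date_ma=10.0),
            CalibrationRow("r", 30, 30, mrca_of="F1|F2", node_date_ma=30.0),
        ])
        # epsilon policy keeps the node where the max rule put it (the share
        # policy would legitimately raise it when resolving the zero terminal
        # branch of the constraining fossil)
        with pytest.warns(UserWarning, match="younger than fossil"):
            scaled = cm.time_scale(self.tree(), cal, mode="main",
                                   zero_policy="epsilon", epsilon=0.1)
        node = scaled.mrca(["F2", "E2"])
        assert node.age == pytest.approx(12.0)
        assert scaled.find_tip("F2").age == pytest.approx(11.9)

    def test_range_mode_extends_fossil_to_last_occurrence(self):
        cal = simple_calibration(node_dates=[CalibrationRow(
            "r", 30, 30, mrca_of="F1|F2", node_date_ma=30.0)])
        scaled = cm.time_scale(self.tree(), cal, mode="range")
        ages = {t.label: t.age for t in scaled.tips()}
        assert ages["F2"] == pytest.approx(6.0)
        assert ages["E1"] == 0.0
        assert scaled.mrca(["F1", "E1"]).age >= 3.8  # constrained by fo

    def test_midpoint_mode(self):
        cal = simple_calibration(node_dates=[CalibrationRow(
            "r", 30, 30, mrca_of="F1|F2", node_date_ma=30.0)])
        scaled = cm.time_scale(self.tree(), cal, mode="midpoint")
        ages = {t.label: t.age for t in scaled.tips()}
        assert ages["E1"] == pytest.approx(1.9)
        assert ages["F2"] == pytest.approx(7.0)

    def test_missing_calibration_is_an_error(self):
        cal = CalibrationTable(rows={"F1": CalibrationRow("F1", 2, 1)})
        with pytest.raises(TreeError, match="E1|missing"):
            cm.time_scale(self.tree(), cal)

    def test_all_durations_positive_after_scaling(self, study, scaled_tree):
        scaled_tree.check_ages(strict=True)
        for node in scaled_tree.preorder():
            if node.parent is not None:
                assert node.duration > 0

    def test_extant_chronogram_reproduced_exactly(self):
        # all-extant ultrametric tree whose molecular dates equal its true
        # node ages
        t, _ = cm.sim_birth_tree(cm.SimConfig(seed=3, n_tips=12,
                                              fossil_fraction=0.0))
        rows, node_dates = {}, []
        for tip in t.tips():
            rows[tip.label] = CalibrationRow(tip.label, fo_ma=0.0, lo_ma=0.0)
        for node in t.internal_nodes():
            a = next(iter(_tips_under(node.children[0])))
            b = next(iter(_tips_under(node.children[1])))
            node_dates.append(CalibrationRow(
                f"{a}|{b}", node.age, node.age,
                mrca_of=f"{a}|{b}", node_date_ma=node.age))
        cal = CalibrationTable(rows=rows, node_dates=node_dates)
        scaled = cm.time_scale(t, cal, mode="main", extend_extant=True)
        for node, orig in zip(scaled.preorder(), t.preorder()):
            assert node.age == pytest.approx(orig.age, abs=1e-9)


def _tips_under(node):
    return [n.label for n in cm.TimeTree(node).tips()]


class TestZeroBranches:
    def chain_tree(self):
        # ((A:0,B:0)X:2,C:3); X and its children all at age 5 under a 2-Myr branch
        t = cm.read_newick("((A:1,B:1)X:2,C:3);")
        t.assign_ages_from_lengths()
        x = t.internal_nodes()[1]
        for c in x.children:
            c.age = x.age  # force zero branches below X
        return t

    def test_share_splits_equally(self):
        # parent==child age 5 below a 2-Myr branch -> both branches 1 Myr
        from chronomorph.tree import TimeTree, TreeNode
        root = TreeNode("r"); root.age = 7.0
        p = root.add_child(TreeNode("p")); p.age = 5.0
        c = p.add_child(TreeNode("c")); c.age = 5.0
        d = c.add_child(TreeNode("tip")); d.age = 0.0
        other = root.add_child(TreeNode("o")); other.age = 0.0
        tree = TimeTree(root)
        out = cm.resolve_zero_branches(tree, policy="share")
        ages = {n.label: n.age for n in out.preorder()}
        assert ages["p"] == pytest.approx(6.0)   # both branches now 1 Myr
        assert ages["c"] == pytest.approx(5.0)   # bottom of chain unchanged
        assert ages["tip"] == 0.0                 # unaffected tip age kept

    def test_epsilon_pushes_child_younger(self):
        from chronomorph.tree import TimeTree, TreeNode
        root = TreeNode("r"); root.age = 7.0
        p = root.add_child(TreeNode("p")); p.age = 5.0
        c = p.add_child(TreeNode("c")); c.age = 5.0
        c.add_child(TreeNode("t1")).age = 0.0
        c.add_child(TreeNode("t2")).age = 0.0
        p2 = root.add_child(TreeNode("t3")); p2.age = 0.0
        out = cm.resolve_zero_branches(TimeTree(root), policy="epsilon",
                                       epsilon=0.1)
        assert {n.label: n.age for n in out.preorder()}["c"] == pytest.approx(4.9)

    def test_no_zero_branches_is_identity(self):
        rng = np.random.default_rng(11)
        t = random_binary_tree(rng, 10)
        out = cm.resolve_zero_branches(t, policy="share")
        for a, b in zip(t.preorder(), out.preorder()):
            assert a.age == pytest.approx(b.age)

    def test_zero_chain_at_root_is_an_error(self):
        from chronomorph.tree import TimeTree, TreeNode
        root = TreeNode("r"); root.age = 5.0
        a = root.add_child(TreeNode("a")); a.age = 5.0
        a.add_child(TreeNode("t1")).age = 0.0
        a.add_child(TreeNode("t2")).age = 0.0
        root.add_child(TreeNode("t3")).age = 0.0
        with pytest.raises(TreeError, match="root"):
            cm.resolve_zero_branches(TimeTree(root), policy="share")


class TestPrune:
    def test_drop_one_tip_preserves_ages(self):
        t = cm.read_newick("((A:1,B:1):2,C:3);")
        t.assign_ages_from_lengths()
        out = cm.prune(t, ["A", "B"])
        assert sorted(out.tip_labels()) == ["A", "B"]
        assert out.root.age == pytest.approx(1.0)
        assert all(tip.age == 0.0 for tip in out.tips())

    def test_keep_all_is_identity(self):
        t = cm.read_newick("((A:1,B:1):2,C:3);")
        out = cm.prune(t, ["A", "B", "C"])
        assert out.to_newick() == t.to_newick()

    def test_patristic_distances_preserved(self):
        rng = np.random.default_rng(23)
        t = random_binary_tree(rng, 50)
        keep = list(rng.choice(t.tip_labels(), size=20, replace=False))
        out = cm.prune(t, keep)
        d_full = t.patristic_distances(labels=sorted(keep))
        d_sub = out.patristic_distances(labels=sorted(keep))
        np.testing.assert_allclose(d_full.to_numpy(), d_sub.to_numpy(),
                                   atol=1e-9)

    def test_unknown_label_rejected(self):
        t = cm.read_newick("((A:1,B:1):2,C:3);")
        with pytest.raises(TreeError, match="ghost"):
            cm.prune(t, ["A", "ghost"])


class TestCalibrationTable:
    def test_csv_roundtrip(self):
        cal = simple_calibration(node_dates=[CalibrationRow(
            "r", 30, 30, mrca_of="F1|F2", node_date_ma=30.0)])
        buf = io.StringIO()
        cal.to_frame().to_csv(buf, index=False)
        buf.seek(0)
        cal2 = CalibrationTable.from_csv(buf)
        assert cal2["F1"].fo_ma == 1.81
        assert cal2.node_dates[0].node_date_ma == 30.0

    def test_invalid_ages_rejected(self):
        with pytest.raises(TreeError):
            CalibrationTable(rows={"x": CalibrationRow("x", fo_ma=1.0, lo_ma=2.0)})
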