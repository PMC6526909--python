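"""Stratigraphic Consistency Index, time-scaling and ghost lineages."""

import numpy as np
import pytest

from morphostrat import (
    AgeTable,
    SciReport,
    ValidationError,
    clade_fad,
    full_resolution_node_count,
    node_is_consistent,
    sci,
    simulate_fossil_ranges,
    timescale,
)
from conftest import ladder_tree, random_binary_tree, tree_from_newick


@pytest.fixture
def fixture_tree():
    return tree_from_newick("((A,B),C);")


@pytest.fixture
def fixture_ages():
    return AgeTable({"A": (10, 1), "B": (8, 0), "C": (5, 0)})


class TestCladeFad:
    def test_tip_is_its_own_fad(self, fixture_tree, fixture_ages):
        tip = [n for n in fixture_tree.tips() if n.label == "B"][0]
        assert clade_fad(fixture_tree, tip, fixture_ages) == 8

    def test_clade_takes_oldest(self):
        tree = tree_from_newick("((A,B),C);")
        ages = AgeTable({"A": (8.7, 0), "B": (5.3, 0), "C": (11.6, 0)})
        node_ab = tree.root.children[0]
        assert clade_fad(tree, node_ab, ages) == 8.7
        assert clade_fad(tree, tree.root, ages) == 11.6

    def test_missing_taxon_named(self, fixture_tree):
        ages = AgeTable({"A": (10, 1), "B": (8, 0)})
        with pytest.raises(ValidationError, match="C"):
            clade_fad(fixture_tree, fixture_tree.root, ages)


class TestNodeConsistency:
    def test_younger_than_sister_is_consistent(self):
        tree = tree_from_newick("(((A,B),C),D);")
        ages = AgeTable({"A": (8, 0), "B": (7, 0), "C": (12, 0), "D": (13, 0)})
        node_ab = tree.root.children[0].children[0]
        assert node_is_consistent(tree, node_ab, ages)

    def test_older_than_sister_is_inconsistent(self):
        tree = tree_from_newick("(((A,B),C),D);")
        ages = AgeTable({"A": (12, 0), "B": (7, 0), "C": (8, 0), "D": (13, 0)})
        node_ab = tree.root.children[0].children[0]
        assert not node_is_consistent(tree, node_ab, ages)

    def test_equal_fads_consistent_unless_strict(self):
        tree = tree_from_newick("(((A,B),C),D);")
        ages = AgeTable({"A": (8, 0), "B": (7, 0), "C": (8, 0), "D": (13, 0)})
        node_ab = tree.root.children[0].children[0]
        assert node_is_consistent(tree, node_ab, ages)
        assert not node_is_consistent(tree, node_ab, ages, strict=True)

    def test_root_rejected(self, fixture_tree, fixture_ages):
        with pytest.raises(ValidationError):
            node_is_consistent(fixture_tree, fixture_tree.root, fixture_ages)


class TestSci:
    def test_report_ratios(self):
        assert SciReport(14, 33).sci_display == 0.42
        assert SciReport(44, 80).sci_display == 0.55

    def test_denominator_is_tips_minus_two(self):
        assert full_resolution_node_count(82) == 80
        assert full_resolution_node_count(35) == 33

    def test_perfect_ladder_scores_one(self):
        # tip fads get younger toward the crown: every node consistent
        tree = tree_from_newick("((((A,B),C),D),E);")
        ages = AgeTable(
            {"A": (2, 0), "B": (3, 0), "C": (5, 0), "D": (8, 0), "E": (11, 0)}
        )
        report = sci(tree, ages)
        assert report.sci == 1.0
        assert report.total == 3

    def test_matches_per_node_enumeration(self, rng):
        labels = [f"t{i}" for i in range(10)]
        for _ in range(10):
            tree = random_binary_tree(labels, rng)
            ages = AgeTable({l: (float(rng.uniform(1, 20)), 0.0) for l in labels})
            report = sci(tree, ages)
            expected = sum(
                node_is_consistent(tree, n, ages)
                for n in tree.internal_nodes(include_root=False)
            )
            assert report.consistent == expected
            assert report.total == len(labels) - 2

    def test_invariant_to_uniform_age_shift(self, rng):
        labels = [f"t{i}" for i in range(8)]
        tree = random_binary_tree(labels, rng)
        fads = {l: float(rng.uniform(1, 20)) for l in labels}
        a1 = AgeTable({l: (f, 0.0) for l, f in fads.items()})
        a2 = AgeTable({l: (f + 7.5, 0.0) for l, f in fads.items()})
        assert sci(tree, a1).consistent == sci(tree, a2).consistent

    def test_partition_by_clade(self):
        tree = tree_from_newick("(((A,B),(C,D)),(E,F));")
        ages = AgeTable(
            {l: (f, 0.0) for l, f in zip("ABCDEF", [2, 3, 9, 1, 5, 6])}
        )
        report = sci(tree, ages, clade=["A", "B", "C", "D"])
        assert report.total == 2  # 4-tip partition

    def test_polytomy_warns_and_counts_actual_nodes(self):
        tree = tree_from_newick("((A,B),C,(D,E));")
        ages = AgeTable({l: (f, 0.0) for l, f in zip("ABCDE", [1, 2, 3, 4, 5])})
        with pytest.warns(UserWarning, match="polytom"):
            report = sci(tree, ages)
        assert report.total == 2

    def test_too_small_partition_rejected(self):
        tree = tree_from_newick("((A,B),C);")
        ages = AgeTable({l: (1.0, 0.0) for l in "ABC"})
        with pytest.raises(ValidationError):
            sci(tree, ages, clade=["A", "B"])


class TestTimescale:
    def test_fixture_ages_and_ghosts(self):
        tree = tree_from_newick("((A,B),C);")
        ages = AgeTable({"A": (10, 0), "B": (8, 0), "C": (5, 0)})
        ts = timescale(tree, ages)
        node_ab = ts.root.children[0]
        assert node_ab.age == 10 and ts.root.age == 10
        ghosts = {n.label: ts.ghost(n) for n in ts.tips()}
        assert ghosts == {"A": 0.0, "B": 2.0, "C": 5.0}

    def test_equal_fads_all_ghosts_zero(self):
        tree = tree_from_newick("((A,B),C);")
        ages = AgeTable({l: (6.0, 0.0) for l in "ABC"})
        ts = timescale(tree, ages)
        assert all(n.age == 6.0 for n in ts.postorder() if not n.is_tip)
        assert ts.total_ghost() == 0.0

    def test_min_branch_pushes_parents_older(self):
        tree = tree_from_newick("((A,B),C);")
        ages = AgeTable({l: (6.0, 0.0) for l in "ABC"})
        ts = timescale(tree, ages, min_branch=1.0)
        node_ab = ts.root.children[0]
        assert node_ab.age == 7.0 and ts.root.age == 8.0

    def test_ghost_sum_identity(self, rng):
        labels = [f"t{i}" for i in range(9)]
        tree = random_binary_tree(labels, rng)
        ages = AgeTable({l: (float(rng.uniform(1, 30)), 0.0) for l in labels})
        ts = timescale(tree, ages)
        total = ts.total_ghost()
        tips_part = sum(ts.ghost(n) for n in ts.tips())
        internal_part = sum(
            n.parent.age - n.age
            for n in ts.postorder()
            if n.parent is not None and not n.is_tip
        )
        assert total == pytest.approx(tips_part + internal_part)
        assert all(
            ts.ghost(n) >= 0 for n in ts.postorder() if n.parent is not None
        )

    def test_parent_never_younger_than_child(self, rng):
        labels = [f"t{i}" for i in range(12)]
        tree = random_binary_tree(labels, rng)
        ages = AgeTable({l: (float(rng.uniform(1, 30)), 0.0) for l in labels})
        ts = timescale(tree, ages)
        for node in ts.postorder():
            if node.parent is not None:
                assert node.parent.age >= node.age

    def test_missing_age_rejected(self):
        tree = tree_from_newick("((A,B),C);")
        with pytest.raises(ValidationError, match="C"):
            timescale(tree, AgeTable({"A": (1, 0), "B": (2, 0)}))


class TestAgainstSimulationTruth:
    def test_perfect_preservation_on_ladder_recovers_everything(self):
        ts_true = ladder_tree(
            [("A", 0.0), ("B", 0.0), ("C", 0.0), ("D", 0.0), ("E", 0.0)],
            [2.0, 4.0, 7.0, 11.0],
        )
        ages, _ = simulate_fossil_ranges(ts_true, "perfect", seed=1)
        report = sci(ts_true, ages)
        assert report.sci == 1.0
        rescaled = timescale(ts_true, ages)
        true_ages = {
            id(n): n.age for n in ts_true.postorder()
        }
        for a, b in zip(ts_true.postorder(), rescaled.postorder()):
            if not a.is_tip:
                assert b.age == pytest.approx(a.age)

    def test_thinning_degrades_sci_monotonically(self):
        # heavier thinning (smaller q => larger mean gap) lowers mean SCI;
        # paired exponential draws make the comparison monotone per replicate
        from morphostrat import simulate_yule_tree

        # gaps stay small relative to lineage durations: beyond that regime
        # FADs clamp onto the LADs and tie-consistency dominates instead
        qs = [8.0, 2.0, 0.5]
        means = []
        for q in qs:
            vals = []
            for rep in range(100):
                ts, _ = simulate_yule_tree(12, 0.25, seed=5000 + rep)
                ages, _ = simulate_fossil_ranges(
                    ts, "uniform_thinning", q=q, seed=9000 + rep
                )
                vals.append(sci(ts, ages).sci)
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]
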