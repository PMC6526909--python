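"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own algorithms: parsimony
steps by exhaustive assignment enumeration, tree-space optima by exhaustive
topology enumeration, Mk transition matrices by scipy's matrix exponential.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from morphostrat.matrix import Cell, CharacterMatrix
from morphostrat.trees import Node, Tree


# ---------------------------------------------------------------------------
# tree construction helpers


def tree_from_newick(text: str) -> Tree:
    """Parse a small Newick string (labels, optional :lengths) directly."""
    import dendropy

    from morphostrat.trees import Tree as MTree

    dtree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    return MTree.from_dendropy(dtree)


def ladder_tree(tip_ages: list[tuple[str, float]], node_ages: list[float]) -> "object":
    """Pectinate time-scaled tree: tips listed crown-to-root; node_ages[i]
    is the age of the node joining tip i+1 to the growing crown clade.
    Every internal node has a terminal child, so tip origins equal node ages.
    """
    from morphostrat.strat import TimeScaledTree

    assert len(node_ages) == len(tip_ages) - 1
    label0, age0 = tip_ages[0]
    current = Node(label0)
    current.age = age0
    for (label, age), node_age in zip(tip_ages[1:], node_ages):
        tip = Node(label)
        tip.age = age
        parent = Node()
        parent.age = node_age
        parent.add_child(current)
        parent.add_child(tip)
        current = parent
    ranges = {}
    tree = Tree(current)
    for tip in tree.tips():
        origin = tip.parent.age if tip.parent else tip.age
        ranges[tip.label] = (origin, tip.age)
    for node in tree.postorder():
        if node.parent is not None:
            node.length = node.parent.age - node.age
    return TimeScaledTree(current, ranges)


def random_binary_tree(labels: list[str], rng: np.random.Generator) -> Tree:
    """Uniform-ish random rooted binary topology by sequential insertion."""
    nodes = [Node(lbl) for lbl in labels]
    order = list(rng.permutation(len(nodes)))
    root = Node()
    root.add_child(nodes[order[0]])
    root.add_child(nodes[order[1]])
    tree = Tree(root)
    for idx in order[2:]:
        candidates = [n for n in tree.postorder() if n is not tree.root]
        target = candidates[int(rng.integers(len(candidates)))]
        parent = target.parent
        joint = Node()
        parent.children[parent.children.index(target)] = joint
        joint.parent = parent
        joint.add_child(target)
        joint.add_child(nodes[idx])
    return tree


def all_topologies(labels: list[str]):
    """Every unrooted binary topology on the labels, returned rooted on the
    first label's pendant edge; (2n−5)!! trees."""

    def grow(trees: list[Tree], label: str) -> list[Tree]:
        out = []
        for tree in trees:
            spots = [n for n in tree.postorder() if n is not tree.root]
            for i in range(len(spots)):
                new = tree.copy()
                spot = [n for n in new.postorder() if n is not new.root][i]
                parent = spot.parent
                joint = Node()
                parent.children[parent.children.index(spot)] = joint
                joint.parent = parent
                joint.add_child(spot)
                joint.add_child(Node(label))
                out.append(new)
        return out

    base = Tree(Node())
    base.root.add_child(Node(labels[0]))
    core = Node()
    base.root.add_child(core)
    core.add_child(Node(labels[1]))
    core.add_child(Node(labels[2]))
    trees = [base]
    for label in labels[3:]:
        trees = grow(trees, label)
    return trees


# ---------------------------------------------------------------------------
# parsimony oracles


def brute_force_steps(tree: Tree, column: list[Cell], taxa: list[str]) -> int:
    """Minimum changes by exhaustive enumeration of internal-node states."""
    cells = dict(zip(taxa, column))
    alphabet = sorted({s for c in column for s in c.states})
    internals = [n for n in tree.postorder() if not n.is_tip]
    best = None
    for assignment in product(alphabet, repeat=len(internals)):
        state = {id(n): s for n, s in zip(internals, assignment)}
        cost = 0
        for node in tree.postorder():
            if node.parent is None:
                continue
            ps = state[id(node.parent)]
            if node.is_tip:
                cost += 0 if ps in cells[node.label].states else 1
            else:
                cost += state[id(node)] != ps
        if best is None or cost < best:
            best = cost
    return best


def brute_force_mpr(tree: Tree, column: list[Cell], taxa: list[str]) -> dict:
    """Per-internal-node set of states over all minimal assignments."""
    cells = dict(zip(taxa, column))
    alphabet = sorted({s for c in column for s in c.states})
    internals = [n for n in tree.postorder() if not n.is_tip]
    best = brute_force_steps(tree, column, taxa)
    sets: dict[int, set] = {id(n): set() for n in internals}
    for assignment in product(alphabet, repeat=len(internals)):
        state = {id(n): s for n, s in zip(internals, assignment)}
        cost = 0
        for node in tree.postorder():
            if node.parent is None:
                continue
            ps = state[id(node.parent)]
            if node.is_tip:
                cost += 0 if ps in cells[node.label].states else 1
            else:
                cost += state[id(node)] != ps
        if cost == best:
            for n in internals:
                sets[id(n)].add(state[id(n)])
    return {n: frozenset(sets[id(n)]) for n in internals}


def random_matrix(
    taxa: list[str],
    n_chars: int,
    rng: np.random.Generator,
    k: int = 3,
    missing_prob: float = 0.15,
    poly_prob: float = 0.1,
) -> CharacterMatrix:
    rows = []
    for _ in taxa:
        row = []
        for _ in range(n_chars):
            u = rng.random()
            if u < missing_prob:
                row.append(None)
            elif u < missing_prob + poly_prob:
                n_poly = int(rng.integers(2, k + 1))
                row.append(set(rng.choice(k, size=n_poly, replace=False).tolist()))
            else:
                row.append(int(rng.integers(k)))
        rows.append(row)
    return CharacterMatrix.from_states(taxa, rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def four_tip_tree():
    return tree_from_newick("((A,B),(C,D));")


@pytest.fixture
def four_tip_matrix():
    # char 1: one step on ((A,B),(C,D)); char 2: two steps
    return CharacterMatrix.from_states(
        ["A", "B", "C", "D"], [[0, 0], [0, 1], [1, 0], [1, 1]]
    )
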