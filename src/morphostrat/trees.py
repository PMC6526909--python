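"""Rooted tree topology with optional branch lengths, node ages and annotations.

The class is intentionally small: parsing and serialisation of Newick/NEXUS
go through dendropy (see :mod:`morphostrat.io`); this module only holds the
in-memory representation the analysis kernels operate on, plus the topology
utilities (clades, bipartitions, MRCA, copying) they share.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import dendropy

from .errors import ValidationError

__all__ = ["Node", "Tree"]


class Node:
    __slots__ = ("label", "children", "parent", "length", "age", "annotations")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.length = length
        self.age: Optional[float] = None
        self.annotations: dict = {}

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'} deg={len(self.children)}>"


class Tree:
    """A rooted tree; tips carry unique taxon labels, polytomies allowed."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal -----------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        return [
            n
            for n in self.postorder()
            if n.children and (include_root or n is not self.root)
        ]

    # -- structure -----------------------------------------------------

    def validate(self) -> None:
        labels = self.tip_labels()
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate tip labels: {', '.join(dup)}")
        if any(l in (None, "") for l in labels):
            raise ValidationError("every tip must carry a non-empty label")
        if self.root.parent is not None:
            raise ValidationError("root must have no parent")

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def n_tips(self) -> int:
        return sum(1 for n in self.postorder() if n.is_tip)

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.age = node.age
            new.annotations = dict(node.annotations)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root))

    def tip_set(self, node: Node) -> frozenset[str]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_tip:
                out.append(n.label)
            else:
                stack.extend(n.children)
        return frozenset(out)

    def clades(self, include_root: bool = False) -> set[frozenset[str]]:
        """Rooted clades (descendant tip sets of internal nodes)."""
        below: dict[int, frozenset] = {}
        out = set()
        for node in self.postorder():
            if node.is_tip:
                below[id(node)] = frozenset([node.label])
            else:
                s = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = s
                if include_root or node is not self.root:
                    out.add(s)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted bipartitions, canonicalised to the side not
        containing the lexicographically first tip label."""
        all_tips = frozenset(self.tip_labels())
        ref = min(all_tips)
        out = set()
        for clade in self.clades(include_root=False):
            side = all_tips - clade if ref in clade else clade
            if 2 <= len(side) <= len(all_tips) - 2:
                out.add(side)
        return out

    def mrca(self, labels: Iterable[str]) -> Node:
        want = set(labels)
        if not want:
            raise ValidationError("empty taxon set for MRCA")
        have = set(self.tip_labels())
        missing = want - have
        if missing:
            raise ValidationError(f"taxa absent from tree: {', '.join(sorted(missing))}")
        counts: dict[int, int] = {}
        node_of: dict[int, Node] = {}
        for node in self.postorder():
            node_of[id(node)] = node
            if node.is_tip:
                counts[id(node)] = 1 if node.label in want else 0
            else:
                counts[id(node)] = sum(counts[id(c)] for c in node.children)
            if counts[id(node)] == len(want):
                return node
        return self.root  # pragma: no cover - loop always returns at root

    # -- serialisation -------------------------------------------------

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=tns)

        def build(node: Node, dnode):
            dnode.edge.length = node.length
            if node.is_tip:
                dnode.taxon = tns.require_taxon(label=node.label)
            else:
                if node.label:
                    dnode.label = node.label
                for child in node.children:
                    build(child, dnode.new_child())

        build(self.root, dtree.seed_node)
        dtree.is_rooted = True
        return dtree

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Tree":
        def build(dnode) -> Node:
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon else dnode.label
                node = Node(normalize_label(label), dnode.edge.length)
            else:
                node = Node(dnode.label, dnode.edge.length)
                for dchild in dnode.child_nodes():
                    node.add_child(build(dchild))
            return node

        tree = cls(build(dtree.seed_node))
        tree.validate()
        return tree

    def newick(self, lengths: bool = False, labels: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                s = node.label
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if labels and node.label:
                    s += str(node.label)
            if lengths and node.length is not None:
                s += f":{node.length:g}"
            return s

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree {self.n_tips()} tips>"


def canonical_bipartition(side: Iterable[str], universe: Iterable[str]) -> frozenset:
    """Canonical key for an unrooted bipartition: the side that does not
    contain the lexicographically first taxon (matching
    :meth:`Tree.bipartitions`)."""
    side = frozenset(side)
    universe = frozenset(universe)
    return universe - side if min(universe) in side else side


def normalize_label(label: Optional[str]) -> Optional[str]:
    """Whitespace-normalise a taxon label: strip, internal spaces → ``_``."""
    if label is None:
        return None
    return "_".join(label.split())
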