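"""Stratigraphic congruence: SCI, minimum-age time-scaling, ghost lineages.

The Stratigraphic Consistency Index is the fraction of internal nodes whose
clade's oldest first-appearance date (FAD) is no older than its sister
lineage's; for a fully resolved rooted tree of T tips the denominator is
T − 2 (the non-root internal nodes).  Time-scaling assigns every internal
node the oldest FAD among its descendants (the minimum-age convention),
optionally pushing parents older to enforce a minimum branch duration, and
measures ghost durations as the gap between a lineage's inferred origin and
its oldest fossil.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .ages import AgeTable
from .errors import ValidationError
from .trees import Node, Tree

__all__ = [
    "SciReport",
    "TimeScaledTree",
    "clade_fad",
    "node_is_consistent",
    "sci",
    "full_resolution_node_count",
    "timescale",
]


@dataclass
class SciReport:
    """Counts behind an SCI value; ``sci`` is kept at full precision and
    ``sci_display`` rounded to 2 decimals."""

    consistent: int
    total: int

    def __post_init__(self):
        if not 0 <= self.consistent <= self.total:
            raise ValidationError("need 0 ≤ consistent ≤ total")

    @property
    def sci(self) -> float:
        return self.consistent / self.total

    @property
    def sci_display(self) -> float:
        return round(self.sci, 2)


def full_resolution_node_count(n_tips: int) -> int:
    """SCI denominator for a fully resolved rooted tree: tips − 2 (the
    internal nodes other than the root)."""
    if n_tips < 3:
        raise ValidationError("SCI needs at least 3 tips")
    return n_tips - 2


def clade_fad(tree: Tree, node: Node, ages: AgeTable) -> float:
    """Oldest first-appearance date among the node's descendant tips (Ma)."""
    tips = tree.tip_set(node) if not node.is_tip else frozenset([node.label])
    return max(ages.fad(t) for t in tips)


def _sister(node: Node) -> Node:
    parent = node.parent
    if parent is None:
        raise ValidationError("the root has no sister lineage")
    others = [c for c in parent.children if c is not node]
    if len(others) != 1:
        raise ValidationError("sister undefined at a polytomy")
    return others[0]


def node_is_consistent(
    tree: Tree, node: Node, ages: AgeTable, strict: bool = False
) -> bool:
    """True iff the clade's first occurrence is no older than its sister's
    (``strict``: strictly younger)."""
    if node.is_tip or node.parent is None:
        raise ValidationError("consistency is defined for internal non-root nodes")
    own = clade_fad(tree, node, ages)
    sis = clade_fad(tree, _sister(node), ages)
    return own < sis if strict else own <= sis


def sci(
    tree: Tree,
    ages: AgeTable,
    subtree_root: Node | None = None,
    clade: list[str] | None = None,
    strict: bool = False,
) -> SciReport:
    """Stratigraphic Consistency Index of the tree or of a named partition
    (the subtree rooted at the given taxa's MRCA)."""
    if clade is not None:
        subtree_root = tree.mrca(clade)
    root = subtree_root if subtree_root is not None else tree.root
    sub = Tree(root)
    n_tips = sub.n_tips()
    if n_tips < 3:
        raise ValidationError("SCI partition needs at least 3 tips")
    internal = [n for n in sub.internal_nodes(include_root=False)]
    fully_resolved = all(len(n.children) == 2 for n in [root] + internal)
    consistent = 0
    for node in internal:
        own = clade_fad(sub, node, ages)
        # at a polytomy the "sister" is the oldest co-sister lineage
        sis = max(
            clade_fad(sub, other, ages)
            for other in node.parent.children
            if other is not node
        )
        if (own < sis) if strict else (own <= sis):
            consistent += 1
    if fully_resolved:
        total = full_resolution_node_count(n_tips)
    else:
        total = len(internal)
        warnings.warn(
            "polytomous tree: SCI denominator is the actual internal-node "
            "count, not tips − 2 (which assumes full resolution)"
        )
    return SciReport(consistent=consistent, total=total)


# ---------------------------------------------------------------------------
# time-scaling


class TimeScaledTree(Tree):
    """A tree whose nodes carry ages (Ma) and whose tips carry observed
    stratigraphic ranges [lad, fad]."""

    def __init__(self, root: Node, tip_ranges: dict[str, tuple[float, float]]):
        super().__init__(root)
        self.tip_ranges = dict(tip_ranges)

    def ghost(self, node: Node) -> float:
        """Ghost duration (Myr) on the branch leading to ``node``: the gap
        between the lineage's inferred origin (parent age) and its first
        record (tip FAD, or the node age for internal lineages)."""
        if node.parent is None:
            return 0.0
        origin = node.parent.age
        first = self.tip_ranges[node.label][0] if node.is_tip else node.age
        return origin - first

    def total_ghost(self) -> float:
        return sum(self.ghost(n) for n in self.postorder() if n.parent is not None)

    def copy(self) -> "TimeScaledTree":
        base = super().copy()
        return TimeScaledTree(base.root, self.tip_ranges)

    def validate_ages(self) -> None:
        for node in self.postorder():
            if node.age is None:
                raise ValidationError("every node must carry an age")
            if node.parent is not None and node.parent.age < node.age - 1e-9:
                raise ValidationError("parent age must be ≥ child age")


def timescale(tree: Tree, ages: AgeTable, min_branch: float = 0.0) -> TimeScaledTree:
    """Minimum-age time-scaling: tip age = FAD; node age = oldest descendant
    age, pushed older by ``min_branch`` Myr per branch when requested."""
    if min_branch < 0:
        raise ValidationError("min_branch must be ≥ 0")
    work = tree.copy()
    missing = [t for t in work.tip_labels() if t not in ages]
    if missing:
        raise ValidationError(f"taxa absent from age table: {', '.join(missing)}")
    for node in work.postorder():
        if node.is_tip:
            node.age = ages.fad(node.label)
        else:
            node.age = max(c.age + min_branch for c in node.children)
    for node in work.postorder():
        if node.parent is not None:
            node.length = node.parent.age - node.age
    ranges = {t: ages.ranges[t] for t in work.tip_labels()}
    out = TimeScaledTree(work.root, ranges)
    out.validate_ages()
    return out
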