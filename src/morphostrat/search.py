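"""Heuristic maximum-parsimony tree search.

Strategy: random-addition starting trees, best-improvement hill-climbing
under NNI/SPR/TBR branch swapping, and an optional parsimony ratchet
(alternating swap rounds on a matrix with a random fraction of characters
up-weighted and on the original weights).  Searches operate on trees rooted
at a designated outgroup terminal, which makes rooted SPR equivalent to
SPR on the unrooted tree; TBR additionally re-roots the pruned subtree.

All stochastic choices flow from a single integer seed through numpy
``SeedSequence`` substreams, so a search is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .matrix import CharacterMatrix, MatrixEncoding
from .trees import Node, Tree

__all__ = [
    "SearchConfig",
    "random_addition_tree",
    "search_mpt",
    "ratchet",
    "hill_climb",
    "strict_consensus",
]

log = logging.getLogger("morphostrat.search")


@dataclass
class SearchConfig:
    seed: int
    n_starts: int = 20
    swap: str = "tbr"
    max_saved_trees: int = 100
    ratchet_iterations: int = 50
    ratchet_perturb_fraction: float = 0.25

    def __post_init__(self):
        if self.n_starts < 1 or self.max_saved_trees < 1:
            raise ValidationError("counts in SearchConfig must be ≥ 1")
        if self.ratchet_iterations < 0:
            raise ValidationError("ratchet_iterations must be ≥ 0")
        if not 0 < self.ratchet_perturb_fraction < 1:
            raise ValidationError("ratchet_perturb_fraction must lie in (0, 1)")
        if self.swap not in ("nni", "spr", "tbr"):
            raise ValidationError(f"unknown swap mode: {self.swap!r}")


# ---------------------------------------------------------------------------
# fast scoring of binary search trees


def _score(tree: Tree, enc: MatrixEncoding, weights: np.ndarray) -> int:
    """Weighted Fitch length of a binary tree, on compressed site patterns."""
    uniq, inverse = enc.unique_columns()
    w = np.bincount(inverse, weights=weights, minlength=uniq.shape[1])
    steps = np.zeros(uniq.shape[1], dtype=np.int64)
    state: dict[int, np.ndarray] = {}
    taxa = enc.taxa
    for node in tree.postorder():
        if node.is_tip:
            state[id(node)] = uniq[taxa[node.label]]
        else:
            left = state.pop(id(node.children[0]))
            right = state.pop(id(node.children[1]))
            inter = left & right
            empty = inter == 0
            steps += empty
            state[id(node)] = np.where(empty, left | right, inter)
    return int(round(float((steps * w).sum())))


# ---------------------------------------------------------------------------
# tree surgery (in place, with undo)


def _insert_above(node: Node, new_child: Node) -> Node:
    """Splice a new internal node into the edge above ``node`` and hang
    ``new_child`` from it; returns the splice node."""
    parent = node.parent
    joint = Node()
    parent.children[parent.children.index(node)] = joint
    joint.parent = parent
    joint.children = [node, new_child]
    node.parent = joint
    new_child.parent = joint
    return joint


def _remove_splice(joint: Node, keep: Node) -> None:
    """Undo :func:`_insert_above`: collapse ``joint`` back to ``keep``."""
    parent = joint.parent
    parent.children[parent.children.index(joint)] = keep
    keep.parent = parent


def _detach(node: Node) -> tuple[Node, Node, int]:
    """Remove ``node``'s parent from the tree, promoting its sibling.
    Returns (grandparent, sibling, index of parent in grandparent)."""
    parent = node.parent
    sibling = parent.children[0] if parent.children[1] is node else parent.children[1]
    grand = parent.parent
    pos = grand.children.index(parent)
    grand.children[pos] = sibling
    sibling.parent = grand
    return grand, sibling, pos


def _candidate_nodes(tree: Tree, outgroup: str) -> list[Node]:
    """Nodes whose parent edge can receive an insertion: everything except
    the root and the outgroup terminal."""
    return [
        n
        for n in tree.postorder()
        if n is not tree.root and not (n.is_tip and n.label == outgroup)
    ]


def _subtree_nodes(node: Node) -> list[Node]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def _copy_subtree(node: Node) -> Node:
    new = Node(node.label, node.length)
    for child in node.children:
        new.add_child(_copy_subtree(child))
    return new


def _rerootings(sub: Node) -> list[Node]:
    """All alternative rootings of a detached binary subtree, one fresh copy
    per unrooted edge (the original rooting is excluded); used by TBR.

    The subtree is viewed as an unrooted tree by splicing out its root
    (joining the root's two children); each remaining edge then induces one
    rooted form.
    """
    if sub.is_tip:
        return []
    members = _subtree_nodes(sub)
    if sum(1 for n in members if n.is_tip) < 3:
        return []  # a cherry has a single unrooted form
    adj: dict[int, list[Node]] = {id(n): [] for n in members if n is not sub}

    def connect(a: Node, b: Node):
        adj[id(a)].append(b)
        adj[id(b)].append(a)

    for n in members:
        if n is sub:
            continue
        for c in n.children:
            connect(n, c)
    left, right = sub.children
    connect(left, right)

    edges = []
    seen = set()
    for n in members:
        if n is sub:
            continue
        for m in adj[id(n)]:
            key = frozenset((id(n), id(m)))
            if key not in seen:
                seen.add(key)
                edges.append((n, m))

    def build(n: Node, frm: Node) -> Node:
        new = Node(n.label if n.is_tip else None)
        for m in adj[id(n)]:
            if m is not frm:
                new.add_child(build(m, n))
        return new

    original = frozenset((id(left), id(right)))
    out = []
    for u, v in edges:
        if frozenset((id(u), id(v))) == original:
            continue
        root = Node()
        root.add_child(build(u, v))
        root.add_child(build(v, u))
        out.append(root)
    return out


# ---------------------------------------------------------------------------
# starting trees


def random_addition_tree(
    matrix: CharacterMatrix,
    seed,
    outgroup: str | None = None,
    weights: np.ndarray | None = None,
) -> Tree:
    """Stepwise-addition starting tree: taxa joined in seeded random order,
    each at the insertion point minimising total parsimony length."""
    if matrix.n_taxa < 3:
        raise ValidationError("random addition requires at least 3 taxa")
    rng = np.random.default_rng(seed)
    enc = matrix.encoding()
    w = enc.weights if weights is None else np.asarray(weights, dtype=np.int64)
    outgroup = outgroup or matrix.taxa[0]
    if outgroup not in enc.taxa:
        raise ValidationError(f"outgroup absent from matrix: {outgroup}")
    rest = [t for t in matrix.taxa if t != outgroup]
    order = [rest[i] for i in rng.permutation(len(rest))]

    root = Node()
    root.add_child(Node(outgroup))
    core = root.add_child(Node())
    core.add_child(Node(order[0]))
    core.add_child(Node(order[1]))
    tree = Tree(root)

    for label in order[2:]:
        tip = Node(label)
        best = None
        for target in _candidate_nodes(tree, outgroup):
            joint = _insert_above(target, tip)
            length = _score(tree, enc, w)
            _remove_splice(joint, target)
            if best is None or length < best[0]:
                best = (length, target)
        _insert_above(best[1], tip)
    return tree


# ---------------------------------------------------------------------------
# branch swapping


def _iter_moves(tree: Tree, outgroup: str, swap: str):
    """Yield (apply, undo) closures for every swap neighbour."""
    if swap == "nni":
        for node in list(tree.postorder()):
            if node.is_tip or node is tree.root or node.parent is tree.root:
                continue
            for i in (0, 1):
                yield _nni_move(node, i)
        return

    prune_candidates = [
        n
        for n in list(tree.postorder())
        if n is not tree.root
        and n.parent is not tree.root
        and not (n.is_tip and n.label == outgroup)
    ]
    for pruned in prune_candidates:
        forms = [pruned]
        if swap == "tbr" and not pruned.is_tip:
            forms += _rerootings(pruned)
        in_pruned = {id(x) for x in _subtree_nodes(pruned)}
        orig_parent = pruned.parent  # moves reassign pruned.parent to joints
        grand, sibling, pos = _detach(pruned)
        targets = [
            n
            for n in list(tree.postorder())
            if n is not tree.root
            and id(n) not in in_pruned
            and not (n.is_tip and n.label == outgroup)
        ]
        for form in forms:
            for target in targets:
                if form is pruned and target is sibling:
                    continue  # reinserting where it came from: original topology
                yield _spr_move(pruned, form, target, grand, sibling, pos)
        # reattach in original position
        grand.children[pos] = orig_parent
        orig_parent.parent = grand
        orig_parent.children = [pruned, sibling]
        pruned.parent = orig_parent
        sibling.parent = orig_parent


def _nni_move(node: Node, i: int):
    def apply():
        parent = node.parent
        sibling = parent.children[0] if parent.children[1] is node else parent.children[1]
        child = node.children[i]
        parent.children[parent.children.index(sibling)] = child
        node.children[i] = sibling
        sibling.parent = node
        child.parent = parent
        return (parent, sibling, child)

    def undo(ctx):
        parent, sibling, child = ctx
        parent.children[parent.children.index(child)] = sibling
        node.children[i] = child
        sibling.parent = parent
        child.parent = node

    return apply, undo


def _spr_move(pruned: Node, form: Node, target: Node, grand, sibling, pos):
    """Regraft ``form`` (the pruned subtree, possibly rerooted) above
    ``target``; the tree is currently in the detached state."""

    def apply():
        joint = _insert_above(target, form)
        return joint

    def undo(joint):
        _remove_splice(joint, target)

    return apply, undo


def hill_climb(
    tree: Tree,
    matrix: CharacterMatrix,
    swap: str = "tbr",
    outgroup: str | None = None,
    weights: np.ndarray | None = None,
    collect_ties: bool = False,
) -> tuple[Tree, int, list[Tree]]:
    """Best-improvement branch swapping until no neighbour is shorter.

    Returns (best tree, best length, equally-long distinct neighbours of the
    final tree when ``collect_ties``).  Length is monotone non-increasing.
    """
    enc = matrix.encoding()
    w = enc.weights if weights is None else np.asarray(weights, dtype=np.int64)
    outgroup = outgroup or tree.root.children[0].label
    current = tree.copy()
    current_len = _score(current, enc, w)
    ties: list[Tree] = []
    tie_keys: set = set()

    improved = True
    while improved:
        improved = False
        best_len = current_len
        best_snapshot = None
        if collect_ties:
            ties, tie_keys = [], set()
        for apply, undo in _iter_moves(current, outgroup, swap):
            ctx = apply()
            length = _score(current, enc, w)
            if length < best_len:
                best_len = length
                best_snapshot = current.copy()
            elif collect_ties and length == current_len:
                key = frozenset(current.bipartitions())
                if key not in tie_keys:
                    tie_keys.add(key)
                    ties.append(current.copy())
            undo(ctx)
        if best_snapshot is not None:
            current = best_snapshot
            current_len = best_len
            improved = True
    if collect_ties:
        own = frozenset(current.bipartitions())
        ties = [t for t in ties if frozenset(t.bipartitions()) != own]
    return current, current_len, ties


# ---------------------------------------------------------------------------
# ratchet


def ratchet(
    matrix: CharacterMatrix,
    config: SearchConfig,
    start: Tree,
    rng: np.random.Generator | None = None,
    outgroup: str | None = None,
) -> Tree:
    """Parsimony ratchet: alternate hill-climbs on perturbed and original
    weights; returns the best tree under the original weights (never worse
    than the hill-climbed start)."""
    if not start.is_binary():
        raise ValidationError("ratchet start tree must be fully resolved")
    rng = rng or np.random.default_rng(config.seed)
    enc = matrix.encoding()
    outgroup = outgroup or start.root.children[0].label

    best, best_len, _ = hill_climb(start, matrix, config.swap, outgroup)
    current = best
    for _ in range(config.ratchet_iterations):
        perturbed = enc.weights.copy()
        chosen = rng.random(matrix.n_chars) < config.ratchet_perturb_fraction
        perturbed[chosen] *= 2
        rough, _, _ = hill_climb(current, matrix, config.swap, outgroup, weights=perturbed)
        current, cur_len, _ = hill_climb(rough, matrix, config.swap, outgroup)
        if cur_len < best_len:
            best, best_len = current, cur_len
    return best


# ---------------------------------------------------------------------------
# multi-start search


def search_mpt(
    matrix: CharacterMatrix,
    config: SearchConfig,
    outgroup: str | None = None,
) -> tuple[int, list[Tree]]:
    """Multi-start heuristic search for most-parsimonious trees.

    Returns the best weighted length found and all distinct topologies at
    that length (bipartition-set identity, capped at
    ``config.max_saved_trees``).
    """
    outgroup = outgroup or matrix.taxa[0]
    enc = matrix.encoding()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_starts)

    best_len: int | None = None
    saved: list[Tree] = []
    saved_keys: set = set()

    def consider(tree: Tree, length: int):
        nonlocal best_len, saved, saved_keys
        if best_len is None or length < best_len:
            best_len = length
            saved, saved_keys = [], set()
        if length == best_len and len(saved) < config.max_saved_trees:
            key = frozenset(tree.bipartitions())
            if key not in saved_keys:
                saved_keys.add(key)
                saved.append(tree)

    for i, child_ss in enumerate(children):
        rng = np.random.default_rng(child_ss)
        start = random_addition_tree(matrix, rng, outgroup)
        start_len = _score(start, enc, enc.weights)
        tree, length, ties = hill_climb(
            start, matrix, config.swap, outgroup, collect_ties=True
        )
        if config.ratchet_iterations > 0:
            tree = ratchet(matrix, config, tree, rng, outgroup)
            length = _score(tree, enc, enc.weights)
            _, _, ties = hill_climb(tree, matrix, config.swap, outgroup, collect_ties=True)
        log.info("replicate %d: start length %d -> final length %d", i + 1, start_len, length)
        consider(tree, length)
        for t in ties:
            consider(t, _score(t, enc, enc.weights))
    return best_len, saved


# ---------------------------------------------------------------------------
# strict consensus


def strict_consensus(trees: list[Tree]) -> Tree:
    """Strict consensus: exactly the clades present in every input tree,
    polytomies where the inputs disagree."""
    if not trees:
        raise ValidationError("strict consensus of an empty tree set")
    tip_sets = [frozenset(t.tip_labels()) for t in trees]
    if len(set(tip_sets)) != 1:
        raise ValidationError("trees must share an identical tip set")
    all_tips = tip_sets[0]
    common = set.intersection(*(t.clades(include_root=False) for t in trees))
    common = {c for c in common if len(c) >= 2}
    clades = sorted(common | {all_tips}, key=lambda c: (-len(c), sorted(c)))

    nodes: dict[frozenset, Node] = {}
    for clade in clades:
        node = Node()
        nodes[clade] = node
        if clade != all_tips:
            parent_clade = min(
                (c for c in clades if len(c) > len(clade) and clade < c),
                key=len,
            )
            nodes[parent_clade].add_child(node)
    for label in sorted(all_tips):
        parent_clade = min((c for c in clades if label in c), key=len)
        nodes[parent_clade].add_child(Node(label))
    root = nodes[all_tips]
    _sort_children(root)
    return Tree(root)


def _sort_children(node: Node) -> str:
    """Deterministic child order (by smallest descendant label); returns
    the node's own smallest label."""
    if node.is_tip:
        return node.label
    keys = [(_sort_children(c), c) for c in node.children]
    keys.sort(key=lambda kc: kc[0])
    node.children = [c for _, c in keys]
    return keys[0][0]
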