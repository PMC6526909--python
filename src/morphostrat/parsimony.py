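"""Parsimony scoring of discrete characters on trees.

The kernel is Fitch's set-intersection algorithm for unordered multistate
characters, run bit-parallel across all characters at once (state-sets are
packed into uint32 bitmasks).  Trees with polytomies are scored by the
equivalent unit-cost dynamic program (Sankoff with a uniform cost matrix),
which is exact for arbitrary out-degree and coincides with Fitch counts on
binary trees.

On top of the step counts the module computes the classical ensemble fit
indices:

    CI = Σ w·m / Σ w·s          (consistency index)
    RI = (Σ w·g − Σ w·s) / (Σ w·g − Σ w·m)   (retention index)
    HI = 1 − CI                 (homoplasy index)
    RC = CI × RI                (rescaled consistency index)

where, per character, ``s`` is the observed step count on the tree, ``m``
the minimum possible on any tree and ``g`` the maximum (the star-tree
count).  Parsimony-uninformative characters (g == m) are dropped from the
RI sums to avoid 0/0.  Most-parsimonious-reconstruction (MPR) ancestral
state-sets are obtained from a two-pass min-cost dynamic program.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import ValidationError
from .matrix import Cell, CharacterMatrix, MatrixEncoding
from .trees import Node, Tree

__all__ = [
    "IndexReport",
    "AncestralStates",
    "fitch_length",
    "char_steps",
    "char_min_steps",
    "char_max_steps",
    "min_steps",
    "max_steps",
    "ensemble_indices",
    "mpr_states",
    "homoplasy_index",
    "rescaled_consistency",
    "truncate",
    "format_indices",
]

_INF = np.int64(1 << 30)


# ---------------------------------------------------------------------------
# step counting


def _tip_rows(tree: Tree, enc: MatrixEncoding) -> dict[int, int]:
    rows = {}
    for tip in tree.tips():
        try:
            rows[id(tip)] = enc.taxa[tip.label]
        except KeyError:
            raise ValidationError(f"tip absent from matrix: {tip.label}") from None
    return rows


def char_steps(tree: Tree, matrix: CharacterMatrix) -> np.ndarray:
    """Per-character minimum step counts of the tree (unweighted)."""
    enc = matrix.encoding()
    if tree.is_binary():
        return _fitch_steps_binary(tree, enc)
    return _sankoff_steps(tree, enc)


def _fitch_steps_binary(tree: Tree, enc: MatrixEncoding) -> np.ndarray:
    rows = _tip_rows(tree, enc)
    steps = np.zeros(enc.masks.shape[1], dtype=np.int64)
    state: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            state[id(node)] = enc.masks[rows[id(node)]]
        else:
            left = state.pop(id(node.children[0]))
            right = state.pop(id(node.children[1]))
            inter = left & right
            empty = inter == 0
            steps += empty
            state[id(node)] = np.where(empty, left | right, inter)
    return steps


def _sankoff_steps(tree: Tree, enc: MatrixEncoding) -> np.ndarray:
    rows = _tip_rows(tree, enc)
    n_chars = enc.masks.shape[1]
    n_states = int(max((max(s) for s in _alphabets(enc)), default=0)) + 1
    bits = (np.arange(n_states, dtype=np.uint32))
    cost: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            masks = enc.masks[rows[id(node)]][:, None]
            allowed = (masks >> bits[None, :]) & 1
            cost[id(node)] = np.where(allowed.astype(bool), 0, _INF)
        else:
            total = np.zeros((n_chars, n_states), dtype=np.int64)
            for child in node.children:
                c = cost.pop(id(child))
                cmin = c.min(axis=1, keepdims=True)
                total += np.minimum(c, cmin + 1)
            cost[id(node)] = total
    return cost[id(tree.root)].min(axis=1)


def _alphabets(enc: MatrixEncoding):
    for j in range(enc.full_masks.shape[0]):
        mask = int(enc.full_masks[j])
        yield [s for s in range(32) if mask >> s & 1]


def tree_length(tree: Tree, matrix: CharacterMatrix) -> int:
    """Weighted total parsimony length Σ w_i · s_i."""
    s = char_steps(tree, matrix)
    return int((s * matrix.encoding().weights).sum())


# ---------------------------------------------------------------------------
# per-character extremes


def char_min_steps(column: list[Cell]) -> int:
    """Minimum steps of one character on any tree.

    Equals (size of the smallest set of states hitting every non-missing
    cell's state-set) − 1; without polymorphism this is the familiar
    (distinct observed states − 1).
    """
    sets = [c.states for c in column if not c.missing]
    if not sets:
        return 0
    alphabet = sorted(set().union(*sets))
    for size in range(1, len(alphabet) + 1):
        for chosen in combinations(alphabet, size):
            chosen_set = set(chosen)
            if all(s & chosen_set for s in sets):
                return size - 1
    return len(alphabet) - 1  # pragma: no cover - loop always hits


def char_max_steps(column: list[Cell]) -> int:
    """Maximum steps on any tree: the star-tree count.

    g = (non-missing cells) − (largest number of cells assignable to a
    single state, resolving polymorphic cells in that state's favour).
    """
    sets = [c.states for c in column if not c.missing]
    if not sets:
        return 0
    alphabet = set().union(*sets)
    best = max(sum(1 for s in sets if a in s) for a in alphabet)
    return len(sets) - best


def min_steps(matrix: CharacterMatrix) -> np.ndarray:
    return np.array([char_min_steps(matrix.column(j)) for j in range(matrix.n_chars)])


def max_steps(matrix: CharacterMatrix) -> np.ndarray:
    return np.array([char_max_steps(matrix.column(j)) for j in range(matrix.n_chars)])


# ---------------------------------------------------------------------------
# ensemble indices


@dataclass
class IndexReport:
    """Tree length plus ensemble fit indices; ``None`` marks an index that
    is undefined for the data (e.g. CI when every character is constant)."""

    length: int
    s: np.ndarray
    m: np.ndarray | None = None
    g: np.ndarray | None = None
    weights: np.ndarray | None = None
    ci: float | None = None
    ri: float | None = None
    hi: float | None = None
    rc: float | None = None

    def to_rows(self) -> list[dict]:
        rows = []
        for j in range(len(self.s)):
            rows.append(
                {
                    "character": j + 1,
                    "weight": int(self.weights[j]) if self.weights is not None else 1,
                    "steps": int(self.s[j]),
                    "min_steps": int(self.m[j]) if self.m is not None else None,
                    "max_steps": int(self.g[j]) if self.g is not None else None,
                }
            )
        return rows

    def to_json_dict(self) -> dict:
        return {
            "length": self.length,
            "ci": self.ci,
            "ri": self.ri,
            "hi": self.hi,
            "rc": self.rc,
            "per_char": self.to_rows(),
        }


def fitch_length(tree: Tree, matrix: CharacterMatrix) -> IndexReport:
    """Score the tree: per-character steps and weighted total length."""
    s = char_steps(tree, matrix)
    w = matrix.encoding().weights
    return IndexReport(length=int((s * w).sum()), s=s, weights=w)


def ensemble_indices(tree: Tree, matrix: CharacterMatrix) -> IndexReport:
    s = char_steps(tree, matrix)
    m = min_steps(matrix)
    g = max_steps(matrix)
    w = matrix.encoding().weights
    S = int((w * s).sum())
    report = IndexReport(length=S, s=s, m=m, g=g, weights=w)
    if S > 0:
        report.ci = float((w * m).sum() / S)
        report.hi = 1.0 - report.ci
    informative = g > m
    denom = int((w[informative] * (g - m)[informative]).sum())
    if denom > 0:
        num = int((w[informative] * (g - s)[informative]).sum())
        report.ri = num / denom
    if report.ci is not None and report.ri is not None:
        report.rc = report.ci * report.ri
    return report


def homoplasy_index(ci: float) -> float:
    """HI = 1 − CI."""
    return 1.0 - ci


def rescaled_consistency(ci: float, ri: float) -> float:
    """RC = CI × RI (full precision; see :func:`format_indices` for display)."""
    return ci * ri


def truncate(x: float, digits: int = 3) -> float:
    """Truncate toward zero at ``digits`` decimals (TNT-style display)."""
    factor = 10**digits
    return math.trunc(x * factor) / factor


def format_indices(report: IndexReport) -> dict:
    """Display form: CI/RI/HI rounded to 3 decimals, RC truncated to 3
    (matching the output convention of the parsimony programs this module
    reproduces)."""

    def r3(x):
        return None if x is None else round(x, 3)

    return {
        "length": report.length,
        "ci": r3(report.ci),
        "ri": r3(report.ri),
        "hi": r3(report.hi),
        "rc": None if report.rc is None else truncate(report.rc, 3),
    }


# ---------------------------------------------------------------------------
# MPR ancestral state-sets


@dataclass
class AncestralStates:
    """Per-node MPR state-sets for one character (states present in at
    least one most-parsimonious assignment)."""

    char_index: int
    steps: int
    states: dict  # Node -> frozenset of states


def mpr_states(tree: Tree, matrix: CharacterMatrix, char_index: int) -> AncestralStates:
    """MPR ancestral state-sets by a two-pass unit-cost dynamic program.

    Restricted to fully resolved (binary) trees; tips report their observed
    state-sets unchanged.
    """
    if not tree.is_binary():
        raise ValidationError("MPR requires a fully resolved (binary) tree")
    enc = matrix.encoding()
    rows = _tip_rows(tree, enc)
    col = matrix.column(char_index)
    alphabet = matrix.state_symbols[char_index]
    n_states = max(alphabet) + 1
    idx = {t: i for t, i in enc.taxa.items()}

    below: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            cell = col[idx[node.label]]
            c = np.full(n_states, _INF, dtype=np.int64)
            for s in cell.states:
                c[s] = 0
            below[id(node)] = c
        else:
            total = np.zeros(n_states, dtype=np.int64)
            for child in node.children:
                c = below[id(child)]
                total += np.minimum(c, c.min() + 1)
            below[id(node)] = total

    best = int(below[id(tree.root)].min())
    unit = 1 - np.eye(n_states, dtype=np.int64)  # cost(s', s) = [s' != s]

    above: dict[int, np.ndarray] = {id(tree.root): np.zeros(n_states, dtype=np.int64)}
    for node in tree.preorder():
        if node.is_tip:
            continue
        for child in node.children:
            sib_cost = np.zeros(n_states, dtype=np.int64)
            for sib in node.children:
                if sib is child:
                    continue
                c = below[id(sib)]
                sib_cost += np.minimum(c, c.min() + 1)
            # parent-state cost vector, then transition to the child state
            parent_total = above[id(node)] + sib_cost
            above[id(child)] = (parent_total[:, None] + unit).min(axis=0)

    states: dict[Node, frozenset] = {}
    for node in tree.postorder():
        if node.is_tip:
            states[node] = col[idx[node.label]].states
        else:
            total = below[id(node)] + above[id(node)]
            states[node] = frozenset(int(s) for s in np.nonzero(total == best)[0])
    return AncestralStates(char_index=char_index, steps=best, states=states)
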