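"""Mk(1) likelihood for discrete characters: equal-rates k-state Markov model.

Transition probabilities have the closed form

    P_ii(t) = 1/k + (k−1)/k · exp(−k·β·t)
    P_ij(t) = 1/k − 1/k · exp(−k·β·t),   i ≠ j

with β = r/(k−1) so that the total leaving rate of every state is ``r``
(expected substitutions per unit branch length).  Likelihoods use
Felsenstein's pruning algorithm with a uniform root prior; marginal
ancestral probabilities come from the standard outside (up-pass) recursion.
``fit_rate`` maximises the summed log-likelihood over ``r`` by bounded 1-D
optimisation, optionally with the variable-characters ascertainment
correction (likelihoods conditioned on a character being variable).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ValidationError
from .matrix import CharacterMatrix
from .trees import Node, Tree

__all__ = ["MkModel", "mk_transition", "mk_loglik", "mk_marginal", "mk_fit_rate"]

_RATE_LO, _RATE_HI = 1e-8, 1e3


@dataclass
class MkModel:
    """k states, uniform exchange rates, uniform 1/k root prior."""

    k: int
    rate: float = 1.0

    def __post_init__(self):
        if self.k < 2:
            raise ValidationError("Mk model needs k ≥ 2 states")
        if self.rate <= 0:
            raise ValidationError("Mk rate must be positive")

    @property
    def beta(self) -> float:
        return self.rate / (self.k - 1)


def mk_transition(model: MkModel, t: float) -> np.ndarray:
    """k×k transition-probability matrix over a branch of length ``t``."""
    if t < 0:
        raise ValidationError("branch length must be non-negative")
    k = model.k
    e = math.exp(-k * model.beta * t)
    off = (1.0 - e) / k
    return np.full((k, k), off) + np.eye(k) * e


def _branch_length(node: Node) -> float:
    t = node.length if node.length is not None else 0.0
    if t < 0:
        raise ValidationError("branch length must be non-negative")
    return t


def _tip_partials(tree: Tree, matrix: CharacterMatrix, char_index: int, k: int) -> dict:
    col = matrix.column(char_index)
    index = {t: i for i, t in enumerate(matrix.taxa)}
    partials = {}
    for tip in tree.tips():
        if tip.label not in index:
            raise ValidationError(f"unscored tip label: {tip.label}")
        cell = col[index[tip.label]]
        v = np.zeros(k)
        if cell.missing:
            v[:] = 1.0  # missing data: all states equally compatible
        else:
            for s in cell.states:
                if s >= k:
                    raise ValidationError(
                        f"state {s} at tip {tip.label} exceeds model k={k}"
                    )
                v[s] = 1.0
        partials[id(tip)] = v
    return partials


def _down_pass(tree: Tree, tip_partials: dict, model: MkModel) -> dict:
    """Conditional likelihoods of the data below each node, per state."""
    partials = dict(tip_partials)
    for node in tree.postorder():
        if node.is_tip:
            continue
        v = np.ones(model.k)
        for child in node.children:
            P = mk_transition(model, _branch_length(child))
            v = v * (P @ partials[id(child)])
        partials[id(node)] = v
    return partials


def mk_loglik(
    tree: Tree, matrix: CharacterMatrix, char_index: int, model: MkModel
) -> float:
    """Log-likelihood of one character under Mk(1) with a uniform root prior."""
    tips = _tip_partials(tree, matrix, char_index, model.k)
    partials = _down_pass(tree, tips, model)
    lik = float(partials[id(tree.root)].sum() / model.k)
    return math.log(lik)


def mk_marginal(
    tree: Tree, matrix: CharacterMatrix, char_index: int, model: MkModel
) -> dict:
    """Marginal posterior state probabilities per node (vectors sum to 1)."""
    tips = _tip_partials(tree, matrix, char_index, model.k)
    below = _down_pass(tree, tips, model)
    k = model.k

    above: dict[int, np.ndarray] = {id(tree.root): np.full(k, 1.0 / k)}
    for node in tree.preorder():
        if node.is_tip:
            continue
        for child in node.children:
            sib = np.ones(k)
            for other in node.children:
                if other is child:
                    continue
                P = mk_transition(model, _branch_length(other))
                sib = sib * (P @ below[id(other)])
            P = mk_transition(model, _branch_length(child))
            above[id(child)] = (above[id(node)] * sib) @ P

    out = {}
    for node in tree.postorder():
        post = above[id(node)] * below[id(node)]
        total = post.sum()
        if total <= 0:
            raise ValidationError("zero likelihood; check the data and branch lengths")
        out[node] = post / total
    return out


def _site_logliks(tree: Tree, matrix: CharacterMatrix, model: MkModel) -> np.ndarray:
    """Per-character log-likelihoods, pruning vectorised across characters."""
    k = model.k
    n_chars = matrix.n_chars
    index = {t: i for i, t in enumerate(matrix.taxa)}
    partials: dict[int, np.ndarray] = {}
    log_scale = np.zeros(n_chars)
    for node in tree.postorder():
        if node.is_tip:
            if node.label not in index:
                raise ValidationError(f"unscored tip label: {node.label}")
            row = matrix.cells[index[node.label]]
            v = np.zeros((n_chars, k))
            for j, cell in enumerate(row):
                if cell.missing:
                    v[j, :] = 1.0
                else:
                    for s in cell.states:
                        if s >= k:
                            raise ValidationError(
                                f"state {s} at tip {node.label} exceeds model k={k}"
                            )
                        v[j, s] = 1.0
            partials[id(node)] = v
        else:
            v = np.ones((n_chars, k))
            for child in node.children:
                P = mk_transition(model, _branch_length(child))
                v = v * (partials.pop(id(child)) @ P.T)
            top = v.max(axis=1)
            top[top == 0] = 1.0
            log_scale += np.log(top)
            partials[id(node)] = v / top[:, None]
    root = partials[id(tree.root)]
    return np.log(root.sum(axis=1) / k) + log_scale


def mk_fit_rate(
    tree: Tree,
    matrix: CharacterMatrix,
    k: int | None = None,
    variable_only: bool = False,
) -> tuple[float, float]:
    """Maximum-likelihood rate over all characters: returns (r̂, logL).

    ``variable_only`` applies the ascertainment correction for matrices
    collected without constant characters.
    """
    if k is None:
        k = max(max(a) for a in matrix.state_symbols) + 1
        k = max(k, 2)
    variable = [
        j
        for j in range(matrix.n_chars)
        if len({s for c in matrix.column(j) if not c.missing for s in c.states}) > 1
    ]
    if not variable:
        warnings.warn("all characters constant: rate driven to the lower bound")
        model = MkModel(k=k, rate=_RATE_LO)
        return _RATE_LO, float(_site_logliks(tree, matrix, model).sum())

    def neg_loglik(log_r: float) -> float:
        model = MkModel(k=k, rate=math.exp(log_r))
        total = float(_site_logliks(tree, matrix, model).sum())
        if variable_only:
            p_const = _prob_constant(tree, matrix, 0, model)
            total -= matrix.n_chars * math.log(1.0 - p_const)
        return -total

    res = minimize_scalar(
        neg_loglik,
        bounds=(math.log(_RATE_LO), math.log(_RATE_HI)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return math.exp(res.x), -res.fun


def _prob_constant(tree: Tree, matrix: CharacterMatrix, char_index: int, model: MkModel) -> float:
    """Probability that a character is constant across the scored tips."""
    k = model.k
    total = 0.0
    tips = {id(t): None for t in tree.tips()}
    for s in range(k):
        partials = {}
        for tip in tree.tips():
            v = np.zeros(k)
            v[s] = 1.0
            partials[id(tip)] = v
        below = _down_pass(tree, partials, model)
        total += float(below[id(tree.root)].sum() / k)
    return min(total, 1.0 - 1e-12)
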