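"""Clade support by nonparametric bootstrap and symmetric resampling.

Bootstrap: each replicate resamples characters with replacement (realised
as a multinomial replicate weight vector — equivalent to materialising the
resampled columns, and much cheaper), reruns the parsimony search and takes
the replicate's strict consensus; a group's support is the percentage of
replicate consensuses containing it.

Symmetric resampling: each character's weight is independently zeroed with
probability p/2, doubled with probability p/2, and left unchanged otherwise
(the up/down perturbation is symmetric, so expected weights are unbiased).
Support is reported as the frequency difference GC = (frequency of the
group) − (frequency of its most frequent contradictory group), in
[−100, 100].
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .matrix import CharacterMatrix
from .search import SearchConfig, search_mpt, strict_consensus
from .trees import Tree

__all__ = ["ResamplingConfig", "SupportTable", "bootstrap_support", "symmetric_resampling"]


def _default_replicate_search() -> SearchConfig:
    # reduced effort per replicate; see docs/methods.md
    return SearchConfig(seed=0, n_starts=3, swap="spr", ratchet_iterations=0)


@dataclass
class ResamplingConfig:
    method: str
    seed: int
    replicates: int = 100
    change_probability: float = 0.33
    search: SearchConfig = field(default_factory=_default_replicate_search)

    def __post_init__(self):
        if self.method not in ("bootstrap", "symmetric"):
            raise ValidationError(f"unknown resampling method: {self.method!r}")
        if self.replicates < 1:
            raise ValidationError("replicates must be ≥ 1")
        if not 0.0 <= self.change_probability <= 1.0:
            raise ValidationError("change_probability must lie in [0, 1]")


@dataclass
class SupportTable:
    """Support values attached to a reference tree's bipartitions; groups
    seen in replicates but absent from the reference land in ``other``."""

    method: str
    replicates: int
    reference: Tree
    values: dict  # frozenset (bipartition side) -> support in % (or GC)
    other: dict = field(default_factory=dict)  # non-reference group -> raw freq %
    raw: dict = field(default_factory=dict)    # reference group -> raw freq % (GC runs)

    def annotated_tree(self, key: str = "support") -> Tree:
        tree = self.reference.copy()
        all_tips = frozenset(tree.tip_labels())
        ref = min(all_tips)
        for node in tree.internal_nodes(include_root=False):
            clade = tree.tip_set(node)
            side = all_tips - clade if ref in clade else clade
            if side in self.values:
                node.annotations[key] = self.values[side]
                node.label = f"{self.values[side]:g}"
        return tree

    def to_rows(self) -> list[dict]:
        rows = []
        for side in sorted(self.values, key=lambda s: (len(s), sorted(s))):
            rows.append(
                {"group": " ".join(sorted(side)), "support": self.values[side]}
            )
        return rows


def _incompatible(a: frozenset, b: frozenset, universe: frozenset) -> bool:
    """Two bipartition sides conflict unless nested, disjoint, or covering."""
    if a <= b or b <= a or not (a & b):
        return False
    return a | b != universe


def _replicate_groups(matrix, weights, config) -> set[frozenset]:
    rep = matrix.with_weights(weights)
    _, best = search_mpt(rep, config.search)
    return strict_consensus(best).bipartitions()


def _support_run(matrix, reference, config, weight_sampler):
    if set(reference.tip_labels()) != set(matrix.taxa):
        raise ValidationError("reference tree tips must equal the matrix taxa")
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(config.replicates)
    ref_groups = reference.bipartitions()
    counts: Counter = Counter()
    for child in streams:
        rng = np.random.default_rng(child)
        weights = weight_sampler(rng)
        for group in _replicate_groups(matrix, weights, config):
            counts[group] += 1
    return ref_groups, counts


def bootstrap_support(
    matrix: CharacterMatrix, reference: Tree, config: ResamplingConfig
) -> SupportTable:
    """Bootstrap frequencies (%) for the reference tree's bipartitions."""
    base = np.asarray(matrix.weights, dtype=np.int64)
    n = matrix.n_chars

    def sampler(rng):
        picks = rng.integers(0, n, size=n)
        return np.bincount(picks, minlength=n) * base

    ref_groups, counts = _support_run(matrix, reference, config, sampler)
    values = {g: 100.0 * counts.get(g, 0) / config.replicates for g in ref_groups}
    other = {
        g: 100.0 * c / config.replicates for g, c in counts.items() if g not in ref_groups
    }
    return SupportTable("bootstrap", config.replicates, reference, values, other)


def symmetric_resampling(
    matrix: CharacterMatrix, reference: Tree, config: ResamplingConfig
) -> SupportTable:
    """Symmetric-resampling GC values (%) for the reference bipartitions."""
    base = np.asarray(matrix.weights, dtype=np.int64)
    p = config.change_probability
    n = matrix.n_chars

    def sampler(rng):
        u = rng.random(n)
        factor = np.where(u < p / 2, 0, np.where(u < p, 2, 1))
        return base * factor

    ref_groups, counts = _support_run(matrix, reference, config, sampler)
    universe = frozenset(matrix.taxa)
    values, raw = {}, {}
    for g in ref_groups:
        freq = 100.0 * counts.get(g, 0) / config.replicates
        contra = max(
            (
                100.0 * c / config.replicates
                for other_g, c in counts.items()
                if _incompatible(g, other_g, universe)
            ),
            default=0.0,
        )
        values[g] = freq - contra
        raw[g] = freq
    other = {
        g: 100.0 * c / config.replicates for g, c in counts.items() if g not in ref_groups
    }
    return SupportTable("symmetric", config.replicates, reference, values, other, raw)
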