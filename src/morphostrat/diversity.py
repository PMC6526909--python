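"""Clade diversity through time on a time-scaled tree.

Every branch of the tree contributes a lineage segment: a tip lineage spans
[lad, parent age] (observed range plus the ghost segment back to its
inferred origin; ``use_lad=False`` stops the young end at the FAD instead),
an internal lineage spans [node age, parent age].  Zero-duration internal
segments (simultaneous splits under minimum-age scaling) are not distinct
rami and are dropped.  A clade subset selects the branches of the subtree
rooted at the named tips' MRCA, including its stem branch; an exclude set
removes a nested subtree's branches, so a clade and its complement
partition the branch set exactly.

Diversity pulses are maximal windows where the binned count rises
monotonically by at least a threshold within a bounded span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .strat import TimeScaledTree
__all__ = [
    "CladeSpec",
    "DiversityCurve",
    "DiversityEvent",
    "lineage_segments",
    "lineage_count",
    "diversity_curve",
    "detect_pulses",
]


@dataclass(frozen=True)
class CladeSpec:
    """Tip-set specification: ``include`` (None = whole tree, or a clade
    name / tip collection) minus ``exclude`` (a nested clade)."""

    include: object = None
    exclude: object = None
    label: str = "all"


def _resolve(spec_part, ts_tree: TimeScaledTree, clades: dict | None) -> frozenset | None:
    if spec_part is None:
        return None
    if isinstance(spec_part, str):
        if clades is None or spec_part not in clades:
            raise ValidationError(f"unknown clade label: {spec_part}")
        tips = clades[spec_part]
    else:
        tips = spec_part
    tips = frozenset(tips)
    if not tips:
        raise ValidationError("empty clade specification")
    return tips


def _branch_ids(ts_tree: TimeScaledTree, tips: frozenset | None) -> set[int]:
    """ids of nodes whose parent branch belongs to the clade: the MRCA's
    subtree including the MRCA's own (stem) branch."""
    if tips is None:
        return {id(n) for n in ts_tree.postorder() if n.parent is not None}
    if len(tips) == 1:
        (label,) = tips
        for tip in ts_tree.tips():
            if tip.label == label:
                return {id(tip)}
        raise ValidationError(f"taxon absent from tree: {label}")
    mrca = ts_tree.mrca(tips)
    out = set()
    stack = [mrca]
    while stack:
        n = stack.pop()
        if n.parent is not None:
            out.add(id(n))
        stack.extend(n.children)
    return out


def lineage_segments(
    ts_tree: TimeScaledTree,
    spec: CladeSpec = CladeSpec(),
    clades: dict | None = None,
    use_lad: bool = True,
) -> list[tuple[float, float]]:
    """(young, old) endpoints in Ma of every counted lineage segment."""
    include = _resolve(spec.include, ts_tree, clades)
    exclude = _resolve(spec.exclude, ts_tree, clades)
    ids = _branch_ids(ts_tree, include)
    if exclude is not None:
        ids -= _branch_ids(ts_tree, exclude)
    segments = []
    for node in ts_tree.postorder():
        if node.parent is None or id(node) not in ids:
            continue
        old = node.parent.age
        if node.is_tip:
            fad, lad = ts_tree.tip_ranges[node.label]
            young = lad if use_lad else fad
            segments.append((young, old))
        else:
            if old - node.age > 0:
                segments.append((node.age, old))
    return segments


def lineage_count(
    ts_tree: TimeScaledTree,
    t: float,
    spec: CladeSpec = CladeSpec(),
    clades: dict | None = None,
    use_lad: bool = True,
) -> int:
    """Number of lineage segments of the subset that cross time ``t`` (Ma)."""
    if t < 0:
        raise ValidationError("time must be ≥ 0 Ma")
    segs = lineage_segments(ts_tree, spec, clades, use_lad)
    return sum(1 for young, old in segs if young <= t <= old)


@dataclass
class DiversityCurve:
    """Binned lineage counts; bins are contiguous half-open intervals
    [t_old, t_young), oldest first."""

    bin_edges: np.ndarray  # (n_bins + 1,) descending, Ma
    counts: np.ndarray     # (n_bins,) int
    label: str = "all"

    def bins(self) -> list[tuple[float, float]]:
        return [
            (float(self.bin_edges[i]), float(self.bin_edges[i + 1]))
            for i in range(len(self.counts))
        ]

    def to_rows(self) -> list[dict]:
        return [
            {"t_old": old, "t_young": young, "count": int(c)}
            for (old, young), c in zip(self.bins(), self.counts)
        ]


def diversity_curve(
    ts_tree: TimeScaledTree,
    bin_width: float = 1.0,
    spec: CladeSpec = CladeSpec(),
    clades: dict | None = None,
    t_oldest: float | None = None,
    use_lad: bool = True,
) -> DiversityCurve:
    """Lineages per time bin: a segment is counted once in every bin its
    duration intersects."""
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    segs = lineage_segments(ts_tree, spec, clades, use_lad)
    if not segs:
        raise ValidationError(f"clade selects no lineages: {spec.label}")
    if t_oldest is None:
        t_oldest = bin_width * math.ceil(max(old for _, old in segs) / bin_width)
    n_bins = int(round(t_oldest / bin_width))
    edges = t_oldest - bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    for young, old in segs:
        for i in range(n_bins):
            t_old, t_young = edges[i], edges[i + 1]
            # bin holds times t with t_young < t ≤ t_old; segments are closed
            if old > t_young and young <= t_old and not (young == old == t_young):
                counts[i] += 1
    return DiversityCurve(bin_edges=edges, counts=counts, label=spec.label)


@dataclass
class DiversityEvent:
    """A detected diversity pulse: count rises by ``rise`` between
    ``start`` (older) and ``end`` (younger) Ma."""

    start: float
    end: float
    rise: int
    label: str = ""

    def __post_init__(self):
        if not self.start > self.end:
            raise ValidationError("event must run older → younger")


def detect_pulses(
    curve: DiversityCurve, min_rise: int = 3, max_span: float = 3.0
) -> list[DiversityEvent]:
    """Maximal monotone count increases of ≥ ``min_rise`` within windows of
    ≤ ``max_span`` Myr, reported oldest-first and non-overlapping."""
    if min_rise < 1:
        raise ValidationError("min_rise must be ≥ 1")
    counts = curve.counts
    edges = curve.bin_edges
    bin_width = float(edges[0] - edges[1]) if len(edges) > 1 else 0.0
    max_bins = max(1, int(round(max_span / bin_width))) if bin_width > 0 else 1
    events = []
    i = 1
    n = len(counts)
    while i < n:
        if counts[i] <= counts[i - 1]:
            i += 1
            continue
        run_start = i  # first rising step of a maximal non-decreasing run
        j = i
        while j + 1 < n and counts[j + 1] >= counts[j]:
            j += 1
        # trim the run to its rising core
        last_rise = max(p for p in range(run_start, j + 1) if counts[p] > counts[p - 1])
        best = None
        for a in range(run_start, last_rise + 1):
            b = min(last_rise, a + max_bins - 1)
            rise = int(counts[b] - counts[a - 1])
            if best is None or rise > best[0]:
                best = (rise, a, b)
        rise, a, b = best
        if rise >= min_rise:
            events.append(
                DiversityEvent(
                    start=float(edges[a - 1]),
                    end=float(edges[b + 1]),
                    rise=rise,
                    label=curve.label,
                )
            )
        i = j + 1
    return events
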