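"""Synthetic trees, character matrices and fossil ranges with known truth.

Every generator is driven by a single integer seed fanned out through
``numpy.random.SeedSequence`` substreams (tree, characters, preservation),
so each stage is independently bit-reproducible.  The returned
:class:`SimulationTruth` records everything the analysis modules are later
asked to recover: the generating topology and node ages, the states at
every node for every character, per-tip lineage origin times and the
preservation parameters.

The ``paper_shaped`` preset mirrors the shape of a large fossil-mysticete
morphological dataset: 82 taxa, 350 unordered characters with 2–6 states,
roughly 30% missing cells, and a tree depth of a few tens of Myr.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ages import AgeTable
from .errors import ValidationError
from .matrix import CharacterMatrix
from .mk import MkModel, mk_transition
from .strat import TimeScaledTree
from .trees import Node, Tree

__all__ = [
    "SimulationTruth",
    "simulate_yule_tree",
    "simulate_mk_matrix",
    "simulate_fossil_ranges",
    "paper_shaped",
]


@dataclass
class SimulationTruth:
    """Ground truth of one simulation stage, regeneratable from (config, seed)."""

    config: dict
    seed: object
    newick: str | None = None
    node_ages: dict = field(default_factory=dict)       # node label/tip -> age Ma
    tip_origins: dict = field(default_factory=dict)     # tip -> origin of its terminal branch
    node_states: dict = field(default_factory=dict)     # char index -> {node key -> state}
    preservation: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed if isinstance(self.seed, int) else str(self.seed),
            "newick": self.newick,
            "node_ages": self.node_ages,
            "tip_origins": self.tip_origins,
            "preservation": self.preservation,
        }


def _label_internals(tree: Tree) -> None:
    i = 0
    for node in tree.postorder():
        if not node.is_tip and node.label is None:
            i += 1
            node.label = f"n{i}"


def simulate_yule_tree(
    n_tips: int,
    birth_rate: float,
    seed,
    death_rate: float = 0.0,
    max_retries: int = 100,
) -> tuple[TimeScaledTree, SimulationTruth]:
    """Constant-rate birth(–death) tree conditioned on ``n_tips`` extant tips.

    Pure birth (the default) yields an ultrametric tree with tips at 0 Ma;
    with extinction, extinct lineages stay in the tree as fossil tips with
    positive ages.  The simulation runs until the waiting time after the
    n-th surviving lineage appears, so the expected root age of a Yule tree
    is Σ_{k=2..n} 1/(λk).
    """
    if n_tips < 3:
        raise ValidationError("need at least 3 tips")
    if birth_rate <= 0 or death_rate < 0:
        raise ValidationError("need birth_rate > 0 and death_rate ≥ 0")
    rng = np.random.default_rng(seed)

    for _ in range(max_retries):
        result = _grow(n_tips, birth_rate, death_rate, rng)
        if result is not None:
            break
    else:
        raise ValidationError("birth–death simulation failed to reach n_tips")
    root, end_times, present = result

    tree = Tree(root)
    _label_internals(tree)
    ages, origins = {}, {}
    for node in tree.postorder():
        end = end_times.get(id(node), present)
        node.age = present - end
        ages[node.label] = node.age
    for node in tree.postorder():
        if node.parent is not None:
            node.length = node.parent.age - node.age
        if node.is_tip:
            origins[node.label] = node.parent.age if node.parent else node.age

    ranges = {t.label: (t.age, t.age) for t in tree.tips()}
    ts = TimeScaledTree(tree.root, ranges)
    ts.validate_ages()
    truth = SimulationTruth(
        config={"n_tips": n_tips, "birth_rate": birth_rate, "death_rate": death_rate},
        seed=None,
        newick=ts.newick(lengths=True),
        node_ages=ages,
        tip_origins=origins,
    )
    return ts, truth


def _grow(n_tips, birth, death, rng):
    """One forward pass; returns None when the clade dies before n_tips."""
    t = 0.0
    counter = [0]

    def new_tip():
        counter[0] += 1
        return Node(f"t{counter[0]}")

    root = Node()
    alive = [root.add_child(new_tip()), root.add_child(new_tip())]
    # end_times: when a lineage stops being a terminal segment — an internal
    # node's end is its split time, an extinct tip's its death time; lineages
    # alive at the end carry no entry and end at the present.
    end_times: dict[int, float] = {id(root): 0.0}

    while True:
        rate = len(alive) * (birth + death)
        t += rng.exponential(1.0 / rate)
        if len(alive) == n_tips:
            # the sampled "present" falls inside this waiting interval
            return root, end_times, t
        is_birth = True if death == 0 else rng.random() < birth / (birth + death)
        node = alive.pop(int(rng.integers(len(alive))))
        end_times[id(node)] = t
        if is_birth:
            node.label = None  # the split lineage becomes an internal node
            alive.append(node.add_child(new_tip()))
            alive.append(node.add_child(new_tip()))
        elif not alive:
            return None


def simulate_mk_matrix(
    ts_tree: TimeScaledTree,
    n_chars: int,
    k: int,
    rate: float,
    missing_frac: float = 0.0,
    seed=None,
) -> tuple[CharacterMatrix, SimulationTruth]:
    """Evolve unordered characters along the tree under Mk(k) at ``rate``
    changes per Myr; mask a random ``missing_frac`` of cells as ``?``.

    ``k`` may be an int (all characters alike) or a sequence of per-character
    state counts (2–6 in the paper-shaped preset).
    """
    if rate <= 0:
        raise ValidationError("rate must be positive")
    if not 0 <= missing_frac < 1:
        raise ValidationError("missing_frac must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    ks = np.full(n_chars, k, dtype=int) if np.isscalar(k) else np.asarray(k, dtype=int)
    if len(ks) != n_chars or (ks < 2).any():
        raise ValidationError("per-character state counts must be ≥ 2")

    nodes = list(ts_tree.postorder())
    states: dict[int, np.ndarray] = {}
    node_states_truth: dict[int, dict] = {}
    order = list(ts_tree.preorder())
    states[id(ts_tree.root)] = np.array(
        [rng.integers(kj) for kj in ks], dtype=np.int64
    )
    # group characters by k so each branch needs one transition matrix per k
    by_k = {int(kj): np.nonzero(ks == kj)[0] for kj in np.unique(ks)}
    for node in order:
        if node is ts_tree.root:
            continue
        t = node.parent.age - node.age
        parent = states[id(node.parent)]
        child = np.empty(n_chars, dtype=np.int64)
        for kj, idx in by_k.items():
            P = mk_transition(MkModel(k=kj, rate=rate), t)
            cum = P.cumsum(axis=1)
            u = rng.random(len(idx))
            child[idx] = (u[:, None] > cum[parent[idx]]).sum(axis=1)
        states[id(node)] = child

    key_of = {id(n): (n.label if n.label else f"node{i}") for i, n in enumerate(nodes)}
    for j in range(n_chars):
        node_states_truth[j] = {key_of[id(n)]: int(states[id(n)][j]) for n in nodes}

    tips = ts_tree.tips()
    rows = []
    mask = rng.random((len(tips), n_chars)) < missing_frac
    for i, tip in enumerate(tips):
        row = [
            None if mask[i, j] else int(states[id(tip)][j]) for j in range(n_chars)
        ]
        rows.append(row)
    matrix = CharacterMatrix.from_states([t.label for t in tips], rows)
    truth = SimulationTruth(
        config={
            "n_chars": n_chars,
            "k": ks.tolist(),
            "rate": rate,
            "missing_frac": missing_frac,
        },
        seed=None,
        newick=ts_tree.newick(lengths=True),
        node_states=node_states_truth,
    )
    return matrix, truth


def simulate_fossil_ranges(
    ts_tree: TimeScaledTree,
    preservation: str = "perfect",
    q: float = 1.0,
    seed=None,
) -> tuple[AgeTable, SimulationTruth]:
    """Fossil first/last appearances sampled from the true lineage durations.

    ``perfect``: FAD = the tip lineage's true origin (its parent node's
    age), LAD = its true end.  ``uniform_thinning``: the FAD is younger than
    the true origin by an exponential gap with mean 1/q (clamped at the
    LAD), emulating incomplete preservation.
    """
    rng = np.random.default_rng(seed)
    ranges = {}
    origins = {}
    for tip in ts_tree.tips():
        origin = tip.parent.age if tip.parent else tip.age
        end = tip.age
        origins[tip.label] = origin
        if preservation == "perfect":
            fad = origin
        elif preservation == "uniform_thinning":
            if q <= 0:
                raise ValidationError("thinning rate q must be positive")
            fad = max(end, origin - rng.exponential(1.0 / q))
        else:
            raise ValidationError(f"unknown preservation mode: {preservation!r}")
        ranges[tip.label] = (fad, end)
    truth = SimulationTruth(
        config={"preservation": preservation, "q": q},
        seed=None,
        tip_origins=origins,
        preservation={"mode": preservation, "q": q},
    )
    return AgeTable(ranges), truth


# ---------------------------------------------------------------------------
# presets


def paper_shaped(seed: int) -> dict:
    """An 82-taxon × 350-character fossil-scale fixture with known truth.

    Yule birth rate 0.11/Myr puts the root near 36 Ma; Mk rate 0.03/Myr
    yields the heavy homoplasy typical of real morphological matrices; 30%
    of cells are masked as missing; fossil ranges use exponential thinning.
    """
    ss = np.random.SeedSequence(seed)
    s_tree, s_k, s_chars, s_fossil = ss.spawn(4)
    ts, tree_truth = simulate_yule_tree(82, birth_rate=0.11, seed=s_tree)
    ks = np.random.default_rng(s_k).integers(2, 7, size=350)
    matrix, char_truth = simulate_mk_matrix(
        ts, n_chars=350, k=ks, rate=0.03, missing_frac=0.30, seed=s_chars
    )
    ages, fossil_truth = simulate_fossil_ranges(
        ts, preservation="uniform_thinning", q=0.5, seed=s_fossil
    )
    return {
        "tree": ts,
        "matrix": matrix,
        "ages": ages,
        "truth": {"tree": tree_truth, "matrix": char_truth, "fossil": fossil_truth},
        "seed": seed,
    }
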