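# Methods

`morphostrat` implements the computational core of a paleo-phylogenetic
workflow for discrete morphological data: maximum-parsimony inference with
ensemble fit indices and resampling supports, probabilistic (Mk) ancestral
states, stratigraphic congruence of a cladogram with the fossil record, and
clade-diversity-through-time analysis. This note records the models, the
conventions chosen where the methods literature leaves room, the numerical
decisions, and what the synthetic-data generator does and does not emulate.

## Parsimony scoring

Characters are unordered and multistate. A cell is a *state-set*: a
singleton for an ordinary score, a larger set for polymorphism, and the
character's full observed alphabet (flagged missing) for `?`. Gaps (`-`)
are scored identically to `?`; unknown and inapplicable are not
distinguished. Per-character non-negative integer weights default to 1.

Step counts on binary trees use Fitch's intersection/union pass, run
bit-parallel across characters (state-sets packed into uint32 bitmasks, so
at most 32 states per character). Trees with polytomies are scored by the
equivalent unit-cost dynamic program over states (Sankoff with a uniform
cost matrix), which is exact for arbitrary out-degree and reduces to Fitch
counts on binary trees; a pairwise-folded bitwise pass would not be exact
at polytomies, which matters because the per-character bounds
`m_i ≤ s_i ≤ g_i` are asserted throughout the test suite.

Per-character extremes:

* `m_i` — minimum steps on any tree: (size of the smallest set of states
  hitting every non-missing cell's state-set) − 1, found by subset
  enumeration over the observed alphabet (alphabets are ≤ 6 states in
  practice, so this is exact and cheap);
* `g_i` — maximum steps: the star-tree count, (non-missing cells) −
  (largest number of cells assignable to one state, resolving polymorphism
  in that state's favour).

Ensemble indices: CI = Σw·m / Σw·s, RI = (Σw·g − Σw·s)/(Σw·g − Σw·m),
HI = 1 − CI, RC = CI·RI. Parsimony-uninformative characters (g = m) are
dropped from both RI sums to avoid 0/0; this convention is stated here
because parsimony programs differ and exact third-decimal agreement between
implementations can hinge on it. If every character is constant the
indices are reported as undefined (`None`), never 0/0. Internally all
indices are kept at full precision; the display layer rounds CI/RI/HI to
3 decimals and *truncates* RC to 3 decimals, matching the output convention
of the parsimony program this package's index reports are meant to be
comparable with (e.g. CI 0.291 × RI 0.756 = 0.219996 prints as 0.219).

MPR ancestral state-sets (states attainable at a node in at least one
most-parsimonious reconstruction) come from a two-pass unit-cost dynamic
program: `below[v][s]` from the leaves, `above[v][s]` from the root, and
the MPR set is `{s : below+above = s_char}`. This is verified against an
exhaustive-assignment oracle in the tests; it is restricted to binary
trees. Tips always report their observed state-sets.

## Tree search

Heuristic search over unrooted topologies, represented as trees rooted at
an outgroup terminal (default: the first matrix taxon); rooted SPR on such
a representation is exactly unrooted SPR. Components:

* random-addition starting trees (taxa joined in seeded random order at
  the length-minimising insertion point; ties broken by traversal order);
* best-improvement hill-climbing under NNI, SPR, or TBR (TBR = SPR plus
  all rerootings of the pruned subtree);
* a parsimony ratchet: each iteration doubles the weight of a random
  fraction (default 0.25) of characters, hill-climbs under the perturbed
  weights, re-climbs under the original weights, and keeps the best;
* multi-start orchestration returning all distinct topologies at the best
  length (identity = bipartition set; capped by `max_saved_trees`).

Scoring during search uses site-pattern compression (identical columns
scored once, weights aggregated). All randomness flows from one integer
seed through `numpy.random.SeedSequence` substreams, so searches are
bit-reproducible; consensus trees are built with children sorted by
smallest descendant label so serialized output does not depend on hash
ordering.

The strict consensus contains exactly the clades present in every input
tree. On exhaustively enumerable problems (≤ 7 taxa, all 945 unrooted
topologies scored) multi-start TBR attains the global optimum in all
tested cases; that is the package's substitute for re-running a published
82-taxon analysis whose deposited matrix is not bundled here.

## Resampling supports

Bootstrap: characters are resampled with replacement; the resample is
realised as a multinomial weight vector (count × base weight), which is
algebraically identical to materialising resampled columns. Each replicate
is searched (reduced effort by default: 3 random-addition starts, SPR, no
ratchet — configurable) and summarised by its strict consensus; a group's
support is the percentage of replicate consensuses containing it.

Symmetric resampling: each character's weight is independently zeroed with
probability p/2 and doubled with probability p/2 (default p = 0.33), an
unbiased up/down perturbation. Support is reported as the frequency
difference GC = freq(group) − freq(most frequent contradictory group),
in [−100, 100]; two groups contradict when they are neither nested nor
disjoint nor jointly covering. Replicate *consensus* trees (not the full
best-tree sets) feed the frequencies; this choice is stated because the
method's common implementations do not document theirs.

A caution recorded from the tests: with two exactly balanced conflicting
character blocks, tied resamples support neither group, so both observed
frequencies sit symmetrically *below* 50% rather than at it; the suite
asserts the symmetry, not a naive 50% expectation.

## Mk(1) ancestral states

The k-state equal-rates Markov model with closed-form transitions
P_ii(t) = 1/k + (k−1)/k·e^(−kβt), P_ij(t) = 1/k − 1/k·e^(−kβt), where
β = r/(k−1) makes r the total leaving rate (expected changes per unit
branch length — per Myr when branches are time-scaled). Likelihoods use
Felsenstein pruning with per-node rescaling (vectorised across characters),
a uniform 1/k root prior, and missing tips as all-ones partials. Marginal
ancestral probabilities use the standard outside recursion. The rate is
fitted by bounded 1-D optimisation of the summed log-likelihood over
log r ∈ [log 1e−8, log 1e3] (`xatol` 1e−8); only the product r·t is
identifiable, so doubling all branch lengths exactly halves the fitted
rate. No ascertainment correction is applied by default (a
variable-characters-only correction is available behind a flag).

Branch lengths for ancestral reconstruction on a cladogram default to the
time-scaled durations (Myr) produced by the stratigraphic module;
all-equal lengths are a configuration away.

## Stratigraphic congruence

Ages are in Ma before present (larger = older); a taxon's range is the
closed interval [LAD, FAD]. The Stratigraphic Consistency Index counts a
non-root internal node as consistent when its clade's oldest FAD is no
older than its sister lineage's oldest FAD (ties consistent; a strict
variant is available). For a fully resolved rooted tree of T tips the
denominator is T − 2; for polytomous consensus trees the actual non-root
internal-node count is used, with a warning, and the "sister" at a
polytomy is the oldest co-sister lineage. A partition SCI is the SCI of
the subtree rooted at a named tip set's MRCA.

Time-scaling is minimum-age: tip age = FAD, node age = oldest descendant
age, optionally pushed older by a per-branch minimum duration. Ghost
durations are parent age − FAD for terminal branches and parent age −
node age for internal ones.

## Diversity through time

Every branch contributes a lineage segment: tip lineages span
[LAD, parent age] (observed range plus ghost; a FAD-only mode stops at the
FAD), internal lineages [node age, parent age]; zero-duration internal
segments (simultaneous splits under minimum-age scaling) are not distinct
rami and are dropped. Curves bin the last 40 Myr by default into 1-Myr
half-open intervals [t, t−1), counting a segment once in every bin it
intersects. A clade subset is the branch set of the subtree rooted at the
clade's MRCA *including its stem branch*; an exclude-set removes a nested
subtree's branches, so a clade and its complement partition the branches
and their per-bin counts add exactly. Because counting is by intersection,
a wide oldest bin can contain the root plus several early splits; the
clean "two root lineages" statement holds for the instantaneous crossing
count at the root age, and the tests phrase it that way.

Diversity pulses are detected as maximal monotone non-decreasing runs of
the binned counts: a run is trimmed to its rising core, a window of at
most `max_span` (default 3 Myr) with the largest rise is selected, and an
event is emitted when that rise reaches `min_rise` (default 3 lineages).
The event spans the older edge of the last pre-rise bin to the younger
edge of the last rising bin. The thresholds formalise what the source
analyses of such curves do by visual inspection, and are configuration,
not biology.

## Synthetic data

The generator provides ground truth for every stage:

* **Trees**: constant-rate birth(–death) simulation conditioned on n
  surviving tips, run one waiting time past the n-th lineage so the
  expected root age of a pure-birth tree is Σ_{k=2..n} 1/(λk) (checked by
  Monte Carlo against the closed form). Extinct lineages, when a death
  rate is set, remain as fossil tips.
* **Characters**: root states uniform, evolution along branches by the
  Mk transitions above, per-character state counts configurable (2–6 in
  the large preset), cells masked missing i.i.d.
* **Fossil ranges**: perfect preservation (FAD = the tip lineage's true
  origin, i.e. its parent node's age; LAD = its true end) or exponential
  thinning (FAD younger than the origin by an Exp(1/q) gap, clamped at
  the LAD).

The `paper-shaped` preset mirrors a large fossil-mysticete matrix: 82 taxa
× 350 characters, states 2–6, 30% missing cells, Yule birth rate 0.11/Myr
(root near 36 Ma, the depth of the crown-mysticete record) and Mk rate
0.03/Myr, which produces the heavy homoplasy (ensemble CI ≈ 0.2–0.3)
characteristic of real morphological matrices. One integer seed fans out
to per-stage substreams, so each stage is independently reproducible.

What the generator does *not* emulate: correlated character evolution,
clade- or time-structured missingness (real fossil taxa are missing blocks
of characters, not random cells), rate heterogeneity across characters or
lineages, and non-uniform preservation through time. Passing tests
therefore demonstrate algorithmic correctness and calibration under the
stated model, not robustness to those real-data pathologies.

Two regime notes discovered during validation and asserted accordingly:
perfect-preservation SCI equals 1.0 on trees in which every internal node
has a terminal child originating at it (pectinate fixtures) — on balanced
trees even perfect knowledge of origins leaves some nodes inconsistent, so
1.0 is not a general truth; and mean SCI degrades monotonically with
heavier thinning only while the expected FAD gap is small relative to
lineage durations — under extreme thinning FADs clamp onto the LADs, ties
proliferate, and tie-consistency pushes SCI back up.

## Pipeline sizes and determinism

The end-to-end pipeline (simulate/load → search → consensus → indices →
support → SCI/time-scaling → ancestral states → diversity/pulses) writes
plain-text outputs and a manifest with the resolved configuration, package
versions, the seed and SHA-256 checksums of every output; a rerun with the
same config is byte-identical. Defaults for the preset run use reduced
search effort (1 random-addition start, NNI swapping, 1 ratchet iteration;
5 bootstrap replicates at 1 start) so a full 82 × 350 run completes in
tens of seconds on one core; all of these are ordinary config keys for
larger analyses. The acceptance script (`scripts/acceptance.py`) sizes its
synthetic checks the same way: exhaustive-enumeration comparisons at ≤ 7
taxa, 50 rate-recovery replicates of 300 characters on 32-tip trees, 100
replicates for the SCI and conservation Monte-Carlo checks.

## File formats

NEXUS `DATA`/`CHARACTERS` blocks (non-interleaved STANDARD data) and TNT
`xread` for matrices; `{..}`/`(..)`/`[..]` polymorphism; letter symbols map
alphabetically (`A` → 10, …) so write∘read is the identity on state-sets.
Per-character weights round-trip through a NEXUS `ASSUMPTIONS`/`WTSET`
block (the TNT writer emits plain xread; weights do not round-trip through
TNT). Trees are Newick or NEXUS TREES blocks via dendropy; ages are
`taxon,fad,lad` CSV, parsed with round-trip float precision so written
tables re-read bit-exactly.

## Known limitations

Ordered/Dollo/Sankoff-cost characters, implied weighting, Bremer support,
jackknifing, other stratigraphic-fit metrics (RCI, GER, MSM*), gamma rate
heterogeneity and stochastic character mapping are out of scope. MPR
requires binary trees. The search kernel is pure numpy/Python: adequate to
~100 taxa at reduced swap effort, not a TNT replacement for thorough
searches on large matrices.
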