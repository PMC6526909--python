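# morphostrat

Parsimony phylogenetics for discrete morphological matrices, with the
stratigraphic and paleodiversity analyses that fossil-based studies hang on
a cladogram. The package is aimed at paleontologists and systematists who
score fossil and living taxa for morphological characters (e.g. a matrix of
82 operational taxonomic units × 350 skull and skeletal characters for
baleen whales) and then want, from one reproducible toolchain:

* **maximum-parsimony tree search** — Fitch scoring of unordered
  multistate characters (missing data and polymorphism included),
  random-addition starts, NNI/SPR/TBR branch swapping, a parsimony
  ratchet, and strict consensus of the equally parsimonious trees;
* **ensemble fit indices** — tree length S = Σ wᵢsᵢ and
  CI = Σwm / Σws, RI = (Σwg − Σws)/(Σwg − Σwm), HI = 1 − CI,
  RC = CI × RI;
* **clade support** — nonparametric bootstrap frequencies and symmetric
  resampling (weight halved-to-zero/doubled with probability p/2 each)
  reported as frequency differences GC ∈ [−100, 100];
* **ancestral states** — most-parsimonious-reconstruction state-sets and
  marginal posteriors under the Mk(1) model
  (P_ii(t) = 1/k + (k−1)/k·e^(−kβt), β = r/(k−1)), with a
  maximum-likelihood rate fit;
* **stratigraphic congruence** — the Stratigraphic Consistency Index
  SCI = (consistent nodes)/(total nodes), with total = tips − 2 for a
  fully resolved rooted tree; minimum-age time-scaling; ghost-lineage
  durations;
* **diversity through time** — lineage counts per Myr bin (observed
  ranges plus inferred ghost rami), clade subsets by include/exclude
  specs, and detection of radiation pulses;
* **synthetic data with known truth** — Yule/birth–death trees, Mk
  character evolution, and fossil ranges under perfect or thinned
  preservation, so every stage is testable against ground truth.

`docs/methods.md` documents the models, conventions and numerical choices.

## Worked example

```python
import morphostrat as ms

# a 10-taxon dataset with known truth: tree, characters, fossil ranges
tree_true, truth = ms.simulate_yule_tree(10, birth_rate=0.3, seed=42)
matrix, _ = ms.simulate_mk_matrix(tree_true, 120, k=3, rate=0.05,
                                  missing_frac=0.2, seed=43)
ages, _ = ms.simulate_fossil_ranges(tree_true, "uniform_thinning", q=1.0, seed=44)

best_len, trees = ms.search_mpt(
    matrix, ms.SearchConfig(seed=1, n_starts=5, swap="tbr", ratchet_iterations=5)
)
print(best_len, len(trees))              # -> 150 4
print(ms.format_indices(ms.ensemble_indices(trees[0], matrix)))
# -> {'length': 150, 'ci': 0.82, 'ri': 0.75, 'hi': 0.18, 'rc': 0.615}

report = ms.sci(trees[0], ages)
print(report.consistent, report.total, report.sci_display)   # -> 4 8 0.5

ts = ms.timescale(trees[0], ages)
curve = ms.diversity_curve(ts, bin_width=1.0)
print(curve.counts.tolist())             # -> [5, 8, 11]
print(ms.detect_pulses(curve, min_rise=2, max_span=3))
# -> [DiversityEvent(start=3.0, end=0.0, rise=6, label='all')]
```

Reading: the heuristic search found four equally parsimonious trees of
150 steps; the ensemble consistency index 0.82 says characters fit the
tree with little homoplasy (HI 0.18); four of the eight scorable nodes are
stratigraphically consistent (SCI 0.50) under the thinned fossil ranges;
and binned lineage counts rise 5 → 8 → 11 over the last three Myr, which
the pulse detector reports as one diversity event with a rise of 6.

The same stages run from the shell on files (NEXUS/TNT matrices, Newick
trees, `taxon,fad,lad` CSV ages):

```
morphostrat search --matrix m.nex --seed 1 --starts 10 --out best.nex
morphostrat score  --matrix m.nex --tree best.nex
morphostrat sci    --tree best.nex --ages ages.csv
morphostrat run    --config run.yaml      # full pipeline + manifest
```

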