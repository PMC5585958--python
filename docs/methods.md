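# Methods

## Model and procedure

Let `T(m) ⊆ U` be the predicted target genes of miRNA `m` over a gene
universe `U`, and for a miRNA group `G` let `T(G) = ∪_{m∈G} T(m)`. For an
annotation category `C ⊆ U`, the biological process overlap of `G` with `C`
is `ω(G, C) = |T(G) ∩ C| / |C|`. Given a query group `Q` of size `s`, the
analysis samples `N` groups `G_1..G_N` uniformly (each a without-replacement
draw of `s` distinct miRNAs from all miRNAs in the interaction table;
groups may repeat across draws) and reports per category

```
p(C) = #{ i : ω(G_i, C) > ω(Q, C) } / N .
```

Because `|C|` is constant per category, comparing overlaps is identical to
comparing intersection counts, which is what the implementation does. The
null is at the miRNA level: it preserves the correlation structure among
target sets and between targeting and annotation, which is exactly what the
gene-level hypergeometric test ignores (see *Bias* below).

Two estimator conventions are provided: the strictly-greater count `k/N`
(default, matching the definition above) and the `(k+1)/(N+1)` variant
(`plus_one_correction`) that never returns 0. A `>=` comparison is available
behind a flag. Random groups are drawn from *all* miRNAs, including the
query's members; a flag excludes them.

Benjamini–Hochberg step-up marking is run once per level over the `m`
tested categories: sort p ascending, find the largest `k` with
`p_(k) ≤ k·α/m`, mark the first `k`. `**` marks significance at α = 0.01,
`*` at 0.05 only; marks are nested by construction. Zero-overlap categories
are excluded from testing (their overlap can never be exceeded negatively;
testing them wastes `N·|C|` probes) and from `m`; they appear in the output
with `NA` p-value and mark rather than a fabricated `p = 1`.

## Set representation

The gene universe indexes every gene of the interaction table (annotation-
only genes are excluded by default — they can never be targeted, so they
cannot contribute to any overlap; a flag includes them, which changes only
the reported `category_size` and the hypergeometric universe). Bit positions
follow sorted gene-id order, making every bit pattern independent of input
row order.

Target sets are fixed-width bit vectors on 64-bit words (numpy `uint64`
arrays). Group unions are bitwise-or folds into an empty accumulator — one
tallied union operation per member, so a pool of `N` groups of size `s`
costs exactly `N·s` unions. Overlap counts use bit-probing: for each of the
category's gene positions, test that bit of the group bitset and increment
a counter — one tallied probe per category gene, so testing a category
against the pool costs `N·|C|` probes. The pool's union bitsets are
materialized once as a single `(N, words)` matrix shared read-only by all
workers; probing is vectorized across the pool. `popcount(bitwise-and)` is
implemented as an independent cross-check of the probe counter and is used
only in tests.

The reference engine (`engine="naive"`) uses plain python sets: unions by
folding, intersection sizes by probing the smaller (category) side into the
group's hash table without materializing the intersection set. It shares
the sampling, exclusion and marking logic, so for the same seed the two
engines must produce byte-identical output files — the package's central
correctness contract, enforced by tests on random scenarios and exactly
verifiable because both paths are integer-exact.

## Determinism and parallelism

A single PCG64 generator seeded from `RunConfig.seed` draws every random
group before any parallel section. Categories are then partitioned into
contiguous chunks across `workers` threads, each reading the shared pool
matrix and writing its own result slice; merged results are sorted by
(p-value, category id), so output is byte-identical for any worker count
and across reruns. Sampling each group costs one `Generator.choice`
(O(population) per draw), which is negligible at the scales exercised here;
at the 10⁶-group accuracy preset sampling takes a few minutes and the
probing dominates regardless.

## Synthetic data generator

The generator emulates the regime of genome-scale target-prediction
exports, not any specific dataset:

* **Target counts** per miRNA follow a rounded log-normal truncated to
  `[min_targets, max_targets]` — prediction exports are strongly
  right-skewed, with a median of tens of genes and a heavy tail into the
  thousands (defaults: log-median 64, log-sd 1.9). The truncated law's mean
  and variance are computed analytically for bookkeeping tests.
* **Correlation** between target sets comes from a shared *hub* pool
  (default 10% of genes): each miRNA draws `Binomial(count, shared_pool_fraction)`
  of its targets from the hub pool, the rest uniformly from the remaining
  genes. At fraction 0 this reduces exactly to uniform sampling; mean
  pairwise target-set overlap increases monotonically with the fraction.
* **Categories** are uniform random gene sets of configurable size
  (default 10–100 genes). `category_hub_bias` optionally draws a fraction
  of each category from the hub pool, reproducing the empirical fact that
  heavily targeted genes are also heavily annotated — the ingredient that
  makes the gene-level test anti-conservative (below).
* **Planting** constructs a known-enriched instance: planted-category genes
  are injected round-robin into the chosen query miRNAs' target lists until
  the union covers the requested fraction; the realized coverage is
  recorded in the `Truth` record along with every other draw.

What the generator does not emulate: real nomenclature, prediction-score
distributions, the GO DAG (annotations are used exactly as given, no
propagation), and gene-level covariates such as 3'UTR length. Passing tests
therefore demonstrate algorithmic correctness and statistical calibration
under a controlled correlation structure, not biological validity of any
particular prediction source.

## Study designs used in validation

**Scaled-down conditions.** Validation scenarios use a few hundred miRNAs
over a 1 500–2 000-gene universe. At such scales the target-count law must
preserve the real-data *ratio* of per-miRNA targets to universe size (a few
percent); transplanting genome-scale absolute counts onto a small universe
makes every group union swallow whole categories, collapsing the overlap
distribution onto its maximum. The calibration scenario
(`calibration_scenario`) therefore uses a log-normal with median 40 of
2 000 genes (2%), sd 1.3, cap 800, with categories of 100–200 genes so the
achievable p-value grid is fine near the 5% tail.

**Null calibration.** 500 query groups are drawn by the run's own sampler,
each tested against one mid-size category with its own independent
2 000-group pool (independent pools keep the 500 significance indicators
i.i.d., so exact binomial bounds apply). Under the strictly-greater
convention the discrete overlap distribution makes `P(p < t)` exceed `t` by
at most the point mass at the tail boundary — about +0.002 in these
conditions, far inside the binomial 99% interval [0.026, 0.076].

**Bias demonstration.** With shared-pool fraction 0.6 *and* categories
drawn half from the hub pool (`bias_scenario`), the one-sided
hypergeometric test rejects for essentially every random group while the
empirical rate stays near 0.05. Both ingredients are necessary: with
uniformly drawn categories the hub genes form a zero-variance component of
the overlap, the overlap distribution is *under*-dispersed relative to the
hypergeometric, and Fisher becomes conservative rather than inflated. The
bias is a property of correlated targeting *and* annotation structure, which
is the regime real data occupy.

## Numerical and edge-case choices

* p-values and proportions print with 7 decimal places — lossless for the
  1/10⁶ grid of the largest preset; `NA` marks excluded categories.
* Output rows sort by (empirical p, category id); `NA` rows follow, sorted
  by id. Ties in BH receive the mark of their step-up rank block.
* `category_size` counts annotated genes retained after universe filtering
  (the only denominator under which count and proportion comparisons
  coincide); pre-filter counts are in the load report.
* Duplicate input pairs collapse silently into the load report; conflicting
  category names keep the first occurrence.
* A query equal to the full miRNA population is allowed: every random group
  is then the same set, so every tested category gets p = 0 under the
  strict convention — documented, not an error.
* Empty-universe, empty-group and width-mismatch states raise typed errors
  that the CLI maps to distinct exit codes; results files are written via
  temp-file-and-rename so no fatal path leaves partial output.

## Known limitations

* Bitsets are dense and rebuilt per run; no compressed/roaring
  representation or persistence (deliberate non-goals).
* Parallelism uses threads over categories; the probing kernel releases the
  GIL inside numpy, but the naive engine gains nothing from extra workers.
* The empirical p-value's resolution is 1/N; sequential/adaptive stopping
  and importance sampling are out of scope.
* No identifier mapping or annotation retrieval: inputs are used exactly as
  given.
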