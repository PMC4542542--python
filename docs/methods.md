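# Methods

This note documents the models, conventions and numerical choices behind
`sedlineage`, in the order data flows through the package.

## Sequence processing

Inputs are pre-aligned, equal-length nucleotide fragments (the package does
no alignment). Clones are dereplicated into sequence types, tallying clone
count, number of samples and number of distinct (sample, PCR) pairs; type
ids are assigned by descending clone count with lexicographic tie-breaks so
ids are reproducible. The verification filter keeps a type only if it was
seen in at least `min_clones` clones (default 2) **and** `min_pcrs`
independent PCRs (default 2). This is the standard logic for excluding
polymerase artefacts from cloned amplicons: a single-base polymerase error
is overwhelmingly unlikely to recur identically in an independent PCR. Both
thresholds are explicit parameters because stricter or looser protocols
exist; with the defaults, simulated libraries (20 clones × 2 PCRs per
template, per-site error 0.001) retain every true template and discard
> 99% of error variants (measured in the test suite at 20 seeded runs).

Coordinates are 0-based half-open everywhere. Pairwise distances are
uncorrected nucleotide differences; under the default `skip_ambiguous`
policy a site contributes only when both characters are unambiguous
A/C/G/T. Distance summaries report means and maxima both as counts and as
percent of the full fragment length L (count/L × 100, one decimal) — the
"x substitutions out of L nucleotides" convention.

## Trees and haplotype networks

Trees are consumed as Newick with branch lengths on every edge; missing
lengths are rejected rather than defaulted, because patristic distances
(path sums of branch lengths) are meaningless without them. Rooting is
irrelevant to path sums, so trees are treated as unrooted for distance
purposes. The neighbor-joining builder is plumbing for synthetic pipelines
(it recovers additive matrices exactly, negative branch-length estimates
are clamped to zero and flagged); trees for real analyses are expected to
come from external phylogenetic inference.

The haplotype network is a **minimum spanning network**: all edges
belonging to any minimum spanning tree of the Hamming distance matrix
(computed by a Kruskal sweep over weight classes — an edge of weight w is
in some MST iff its endpoints lie in different components of the sub-weight
graph), plus every edge no longer than the largest MST edge plus `epsilon`.
Edges of length d > 1 are expanded through d − 1 inferred intermediate
nodes, so every edge in the final graph is one substitution; inferred nodes
are flagged and carry no annotation. MSN was chosen over alternatives
(TCS, median-joining) because it is fully specified, deterministic and
testable against an MST oracle; median-joining is out of scope. Node
annotations are either vegetation-type proportions (the lineage's affinity
row normalized to sum 1) or the scalar Larix affinity.

## Affinity statistics

With presence/absence data, the "mean relative frequency of a lineage in a
category, corrected for category size" reduces exactly to the within-
category occupancy proportion: presences in the category divided by samples
in the category. That is the implemented definition; it is invariant to
duplicating every sample of a category (property-tested). Row
normalization (dividing by the row sum) is available but off by default.
The Larix pollen affinity of a lineage is the mean Larix percentage of the
samples it occupies — a convex combination of occupied samples' values,
undefined (excluded with a warning, never zero) for lineages observed
nowhere. Affinity-space distances are Euclidean between affinity vectors
(absolute difference for scalars), with Manhattan as an option; the
affinity *columns*, not these distances, are what the constrained
ordinations consume.

## Ordination and inference

**Bray–Curtis** on binarized data equals the Sørensen dissimilarity;
binarization is applied by default because clone frequencies are at best
semi-quantitative. A pair of all-empty samples is defined as distance 0
(with a warning).

**PCoA** is classical scaling: Gower-center −½ J D² J, eigendecompose,
scale eigenvectors by √λ. Bray–Curtis and patristic matrices need not be
Euclidean, so negative eigenvalues occur; the default policy `drop` keeps
positive axes only and reports total inertia as the sum of positive
eigenvalues, with Lingoes and Cailliez corrections available.

**NMDS** minimizes Kruskal stress-1,
√(Σ(d − d̂)² / Σ d²), where d are configuration distances and d̂ their
monotone (isotonic, primary tie-breaking) regression on the input
dissimilarity order. Optimization alternates the isotonic fit with a
Guttman-transform update; 20 starts by default (one from PCoA, the rest
random), convergence when stress improves by < 1e−6 within 300 iterations,
best start returned centered and rotated to principal axes. Stress-1 is
scale-invariant. Presence/absence Bray–Curtis matrices have heavily tied
values, and primary tie-breaking then permits near-zero stress; low stress
on such data says little beyond the tie structure.

**RDA** column-centers the response Y and projects it onto the explanatory
space (intercept included): R² = ‖Ŷ‖²/‖Y_c‖², adjusted
R² = 1 − (1 − R²)(n − 1)/(n − m − 1) with m the explanatory rank,
pseudo-F = (R²/m)/((1 − R²)/(n − m − 1)). Significance comes from
permuting the rows of X, n_perm = 999 by default, with the add-one
estimator p = (1 + #{R²_perm ≥ R²})/(1 + n_perm) — exact under
exchangeability (empirical size 0.05 at 1000 null datasets in the test
suite). **dbRDA** applies RDA to all retained PCoA axes of a distance
matrix, so on Euclidean distances of raw data it reproduces raw-data RDA
to numerical precision (the module's core oracle, < 1e−15 observed).

**Forward selection** is greedy: at each step the candidate adding the most
R² is tested by permuting its residuals off the current model (conditional
test), entering if p < alpha (default 0.1, the single stopping rule); ties
in R² break lexicographically. The reported final-model R², adjusted R²
and p come from a fresh global permutation test of the selected set. When
nothing is selected, the best single candidate's diagnostics are reported,
marked `(none)`. Note the selection step makes the *reported* p of a
selected model optimistic under the null (measured ≈ 0.10–0.12 at
α_entry = 0.1 versus the nominal 0.05) — inherent to select-then-test
reporting, and worth remembering when reading the pipeline's result rows.

## The synthetic study generator

The generator emulates the study design end to end, with retained ground
truth:

* **Tree** — Yule pure-birth: exponential waits with rate k at k extant
  lineages, one extra wait after the last split so terminal branches are
  positive, rescaled to unit root-to-tip height. Ultrametric, n − 1
  internal nodes.
* **Sequences** — Jukes–Cantor along the tree: per-branch per-site
  substitution probability ¾(1 − e^(−4μt/3)); default μ = 0.04 per site
  per unit height gives ~5% mean pairwise divergence on 67-bp fragments,
  the magnitude typical of closely related intra/inter-specific lineages.
* **Lakes** — 21 lakes in 3 contiguous transect blocks of 7; the
  vegetation gradient (arctic tundra → single-tree tundra → forest tundra
  → northern taiga) cycles identically within each block, so every
  transect has the same vegetation composition and the two factors are
  crossed, not confounded (with 21 = 3 × 7 lakes a 1-lake imbalance per
  block is unavoidable). Limnological columns are decorative.
* **Niches** — each lineage's optimum evolves by Brownian motion on the
  true tree (variance `niche_signal` per unit branch length, root at the
  gradient center), then is folded into [−0.5, K − 0.5] by reflection:
  unbounded BM walks off the sampled gradient and produces unobservable
  lineages, and reflection is the standard bounded-trait fix that keeps
  relatedness → niche similarity. Presence is Bernoulli with
  P = baseline · exp(−(optimum − category)²/(2 · width²)) on the
  vegetation axis (environment scenario), the transect axis (geography),
  or constant baseline (null). All-zero lineage rows are redrawn (≤ 100
  retries, then an error): an unobserved lineage cannot enter any
  analysis.
* **Core** — 20 horizons on monotone depth/age grids (~0.019 cm/yr); the
  Larix % curve declines linearly from 6% (oldest) to 1% (youngest) plus
  clipped Gaussian noise (σ = 0.3). Presence uses the same Gaussian niche
  rule with Larix % as the axis, mapping each category-scale optimum
  linearly onto the Larix range (taiga-end optima → high Larix) and
  rescaling the width identically. Empty horizons are legitimate and kept.
* **Clones** — independent per-site errors to a uniform different base,
  round-robin tagging over (default 2) independent PCRs.

Everything is a pure function of (config, seed); `simulate_dataset` spawns
one sub-stream per stage from the seed.

Defaults are the study-scale condition (14 lineages); `strong_preset`
raises the lineage count to 23 — the size of the study's longer-fragment
lineage set — for scenario-recovery checks, with niche width 0.5
category-index units, baseline occupancy 0.9 and Brownian variance 2.0.
Variance 2.0 balances two failure modes: much lower and the optima cluster
at the gradient center (no affinity contrast); much higher and reflection
decorrelates optima from the tree (no relatedness signal).

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: PCR amplification bias and chimeras, indels
and rate heterogeneity, spatial autocorrelation among neighboring lakes,
taphonomic DNA degradation gradients down-core, dating uncertainty, and
any confounding between vegetation and geography (real treeline transects
are confounded by construction; the generator deliberately crosses the
factors to make the scenarios identifiable).

**Detectability frontier.** With these conditions the environment scenario
yields a significant vegetation-affinity dbRDA (forward-selected row,
p < 0.05) in ≈ 70% of 200 seeded runs and a significant transect row in
≈ 25%; the geography scenario mirrors this (≈ 65% / ≈ 21%). These rates
sit at a measurable ceiling: even using the *true* niche optimum as the
explanatory variable — no affinity estimation noise at all — the dbRDA
rejects in only ≈ 68% of runs, because a single Brownian realization on
23 tips explains a bounded share of ultrametric patristic structure. The
plain (no-selection) dbRDA test is exactly calibrated under the null but
has power ≈ 0.5–0.6 here. Power beyond this would require more lineages,
more lakes, or stronger-than-Brownian clade determinism of niches.

## Pipelines

`run_spatial` excludes (with warnings) lineages absent from the tree or
never observed, binarizes occurrence, and emits: NMDS (k = 2) of samples
on Bray–Curtis; RDA of occurrence on transect and vegetation dummies
(reference level dropped; fits are invariant to the choice); dbRDA of
patristic distances on transect-affinity and vegetation-affinity columns —
each with forward selection, one result row per test. `run_temporal`
computes Larix affinities over horizons with non-missing Larix %, requires
≥ 3 observed lineages and non-constant affinity, and runs the
single-candidate dbRDA; it also emits the per-horizon presence × Larix
table. `run_comparison` partitions two same-fragment lineage sets into
shared (identical sequence), exclusive, and near-matching (≤ 2 differences
by default) lineages, attaching affinity context when provided.
`summarize_lakes` uses linear-interpolation quantiles (sorted position
1 + p(n − 1)); this is the convention under which the bundled 21-lake
table reproduces its published median/quartile rows exactly, cell for
cell. Reports are deterministic given (inputs, seed).

## Known limitations

* Affinity statistics assume presence/absence; abundance-weighted variants
  are deliberately out of scope.
* The reported p of a forward-selected model is selection-biased (above).
* dbRDA under the `drop` policy ignores the negative-eigenvalue part of
  non-Euclidean distance structure; Lingoes/Cailliez change R² somewhat.
* The NJ builder and the MSN `epsilon` relaxation are conveniences, not
  substitutes for model-based phylogenetics or network inference.
* Scenario recovery rates are bounded by the Brownian-trait ceiling
  described above; they characterize the test's sensitivity under this
  generator, not the effect size of any real dataset.
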