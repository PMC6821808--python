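# Methods

## Graph model and conventions

A connectome is a dense symmetric nonnegative `N × N` matrix with zero
diagonal; adjacency is positive weight. Matrices are held dense (the target
scale is `N ≤ ~1000`, where dense linear algebra is simpler and faster than
sparse bookkeeping). Node order is file order and every vector or matrix in
the package is aligned to it, so per-subject results join stably across a
cohort.

Input validation is strict and specific: non-square tables, negative
weights and NaN cells each raise a distinct error naming the offending
cell. Asymmetry up to a relative 1e-9 is silently averaged away (nominally
symmetric tractography output), between 1e-9 and 1e-6 averaged with a
warning, and beyond 1e-6 rejected as a corrupt file. The hop distance
between disconnected nodes is floating infinity, never a large finite
sentinel — efficiency sums treat unreachable pairs as contributing zero,
and a magic number would silently corrupt them.

## Optimal transport

The Wasserstein-1 distance is the optimum of the transportation linear
program, solved exactly with HiGHS (`scipy.optimize.linprog`). The contract
is the optimal *value* to 1e-9; the optimal plan need not be unique and no
test depends on which vertex the solver returns. Zero-mass support points
are dropped before solving to keep the polytope nondegenerate.

Two independent paths exist and are cross-checked:

* the plain LP over the full coupling polytope;
* a fast path for metric costs (`assume_metric=True`) that first holds
  mass common to both measures in place at zero cost and solves the LP on
  the residual measures only. For a cost that is a metric (zero between
  identical points, triangle inequality) this reduction is exact; hop
  distances qualify. It is the path the curvature code uses, because the
  neighbourhoods of adjacent nodes overlap heavily and the residual
  problem is much smaller.

A deliberately naive exhaustive enumerator over integer transport plans
(supports ≤ 4, masses in units of `1/L`) serves as the independent oracle;
it shares no code with the LP path.

## Curvature

`κ(x, y) = 1 − W₁(p_x, p_y)/d(x, y)` with the hop-distance geodesic:
weights shape the neighbourhood measures but never the ground metric. The
cost matrix is the hop distance restricted to `supp(p_x) × supp(p_y)`,
computed on the *whole* graph, so transport may route through nodes outside
the two neighbourhoods. Endpoint order is canonicalized before solving,
making `κ(x, y) = κ(y, x)` exact rather than up-to-solver-tolerance.

Bounds: `W₁ ≥ 0` gives `κ ≤ 1`; supports of adjacent nodes lie within 3
hops of each other, so `W₁ ≤ 3` and `κ ≥ −2`. Both node aggregates
(`κ_x` summed, `κ̃_x` weighted by `p_x`) are computed from one edge table
pass. Isolated nodes get node curvature 0, not NaN: deletion cascades
produce isolated nodes routinely and the downstream statistics must stay
total. The same convention excludes them from the node-mean network
average. Global weight rescaling leaves every curvature unchanged, since
`p_x` is weight-normalized and the geodesic is combinatorial.

## Classical measures

* **Strength** is the weight-matrix row sum and coincides with the `d_x`
  normalizer of `p_x`.
* **Betweenness** sums `σ_jk(i)/σ_jk` over unordered pairs, unnormalized.
  Default edge length is `1/w` (strong connections are short), the common
  convention for connectivity matrices; hop mode serves binarized
  analyses. Which convention a published map used is often unstated, so
  both are exposed and the choice is logged in the run manifest.
* **Clustering** binarizes the graph and reports the realized fraction of
  neighbour–neighbour edges, `2·T_i/(k_i(k_i−1))`, zero below degree 2.
* **Global efficiency** is the mean inverse shortest-path length over
  ordered pairs, normalized by the *current* `N(N−1)` — along a cascade
  the graph shrinks and each step is normalized to its own size.
* **Entropy** is the entropy rate of the weight-proportional random walk,
  `S = −Σ_x π_x Σ_y p_x(y) ln p_x(y)` with `π_x = d_x/Σ d_z`, in nats.
  This discrete walk-based entropy is the package's documented robustness
  entropy; it is maximal (`ln(n−1)`) on a complete graph and zero on a
  single edge.

## Deletion cascades

Each step removes the arg-max node of the chosen measure (row and column),
then records largest component, hop-mode efficiency and entropy **of the
remaining graph** — metrics are "after removal", and once the graph is
too small for a metric (one node, or no edges) that metric records 0 so
trajectories always run to completion. Ties at the maximum prefer
non-isolated nodes, then the lowest node index, so trajectories are
deterministic. `recompute=False` freezes the initial ranking (the ablation
variant); `measure="random"` is the seeded null control. The decay-area
statistic (trapezoidal AUC over steps) compares how fast different
targeting rules degrade a global metric.

## Gaussian weight re-mapping

Positive upper-triangle weights are ranked (average ties) and mapped to
`mean + sd · Φ⁻¹(r/(m+1))`; zeros stay zero and symmetry is preserved.
Defaults `mean = 0.5`, `sd = 0.1` follow the convention of prior lesion
analyses; both are flags, because the mapped range genuinely matters — a
mapping that compresses `[1, 1000]` into a narrow band rescales relative
node importance and can change which measure looks most "robust". Mapped
values that come out nonpositive (possible only with extreme parameter
choices) are clipped to 1e-9 with a warning rather than silently deleting
edges.

## Group comparison

Per node: unpaired two-sided t-test with pooled variance — the
homoscedasticity assumption is the documented default, Welch is an opt-in
flag. Nodes with zero pooled variance get `t = 0`, `p = 1` and a flag
instead of a division by zero. Family-wise error over the `m = N` tests is
controlled by the Holm–Šidák step-down: sort p ascending and reject
`p_(i)` iff every `p_(j)`, `j ≤ i`, satisfies
`p_(j) ≤ 1 − (1−α)^{1/(m−j+1)}`. Decisions come from these exact
thresholds; Šidák-adjusted p-values (monotonized) are reported only as a
convenience. The decision path is cross-checked against
`statsmodels.multipletests(method="holm-sidak")` in the tests.

Consistency maps mark each subject's top `⌈fraction·N⌉` nodes by a measure
(ties at the cutoff resolved toward the lower index, for determinism) and
count marking subjects per node. Cross-measure Pearson correlations are
computed per subject; subjects in which a measure is constant are skipped
with a flag rather than producing NaN.

## Synthetic data

The generator emulates three properties of parcellated structural
connectomes that the analyses rely on:

* **exponential weights** — tractography streamline counts are
  approximately exponentially distributed; weights are i.i.d. exponential
  with mean `weight_scale` (default 1, the scale is irrelevant to
  curvature by scale invariance);
* **modular topology** — a stochastic block model with `n_modules = 4`
  communities and a 4× within/between edge-probability ratio, calibrated
  to an overall density of 0.15, typical of parcellated streamline
  networks after tractography. Modularity makes curvature, strength and
  betweenness heterogeneous across nodes the way real connectomes are; a
  homogeneous Erdős–Rényi graph would make top-quantile maps and targeted
  cascades degenerate;
* **cohort structure** — one edge backbone per cohort with weights redrawn
  independently per subject, giving the within-group variance the t-tests
  need; group differences are injected by scaling (or removing) all edges
  incident to chosen target nodes in group B.

All randomness flows from one master seed through spawned
`SeedSequence` streams, so cohorts are reproducible subject-by-subject at
any size.

What the generator does **not** emulate: spatial embedding and
distance-dependent connection probability, heavy-tailed hub degree
distributions, measurement noise correlated across edges, or
subject-level covariates. Tests passing on these synthetics demonstrate
the correctness and statistical calibration of the machinery, not
neuroscientific validity on real tractography data.

## Problem sizes and numerical choices

The test and acceptance workloads use 116-node connectomes (the
low-resolution AAL-like scale) for curvature and cascade analyses and
333-node cohorts (Gordon-atlas scale, 20+20 subjects) for the group
statistics; the family-wise error rate is estimated over hundreds of null
replicates and effect recovery over 100 effect replicates, with node
strength as the tested measure (the injected effect acts directly on
incident weights, hence on strength). Exhaustive curvature oracles run on
every graph with up to 5 nodes plus sampled 6-node graphs, the feasibility
domain of the enumeration oracle (supports ≤ 4).

Tolerances: LP optimum and feasibility 1e-9; oracle agreement 1e-7 (two
independent exact methods, allowing accumulated floating error); mass
normalization 1e-12. Small-graph shortest-path test fixtures use
power-of-two weights so inverse-weight path lengths are exact in floating
point and co-optimal-path counting is solver-independent.

## Known limitations

* Curvature cost grows as one LP per edge; at 1000 nodes and realistic
  density a full edge table takes minutes, and curvature-targeted cascades
  (an LP sweep per removal) are quadratic in that cost — use strength or
  betweenness targeting for large exploratory sweeps.
* The walk-entropy stand-in is one of several "topological entropy"
  definitions in use; comparisons across publications should check which
  definition was used.
* No spatial or geometric null models; the block-model generator is a
  statistical, not biophysical, surrogate.
* Only two-group designs; no regression on continuous covariates (age
  trends, symptom scores) beyond per-subject correlation against an
  arbitrary covariate vector.
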