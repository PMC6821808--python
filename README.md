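# curvnet

Curvature-based robustness analysis of brain structural connectivity
networks.

Structural connectomes — weighted graphs whose nodes are atlas parcels and
whose edge weights are tractography streamline counts — are often summarized
by nodal measures such as strength, betweenness centrality and clustering.
`curvnet` adds a geometric measure: the **Ollivier–Ricci curvature**, a
discrete analogue of Ricci curvature that captures how well the
neighbourhoods of adjacent nodes can be transported into one another.
Positively curved edges sit in redundant, well-clustered circuitry; negatively
curved edges are bridge-like and fragile. Curvature is linked, through the
geometry-entropy connection, to a network's ability to return to equilibrium
after perturbation, which makes it a natural candidate for quantifying the
robustness and fragility of brain regions.

## The model

For an undirected weighted graph `G = (V, E, W)` each node `x` carries a
neighbourhood probability measure

    p_x(y) = w_xy / d_x,     d_x = Σ_{y ∈ N(x)} w_xy.

The curvature of an edge `(x, y)` is

    κ(x, y) = 1 − W₁(p_x, p_y) / d(x, y),

where `W₁` is the Wasserstein-1 (earth mover's) distance computed by an
exact linear program and `d` is the hop distance (edge count of the shortest
path) on the whole graph — for adjacent nodes `d(x, y) = 1`. Node-level
summaries are the scalar node curvature `κ_x = Σ_{y∈N(x)} κ(x, y)`, the
weighted variant `κ̃_x = Σ_y p_x(y) κ(x, y)`, and the network average of
`κ_x` over non-isolated nodes.

Around the curvature core the package provides:

* classical comparators — strength, betweenness, clustering, global
  efficiency, and the entropy rate of the weight-proportional random walk;
* targeted node-deletion cascades (remove the currently strongest /
  most-central / most-curved node, re-measure, repeat) with a random-order
  control, tracking largest component, efficiency and entropy;
* a rank-preserving Gaussian re-mapping of edge weights (streamline counts
  are approximately exponentially distributed);
* two-group per-node comparison: pooled-variance two-sided t-tests with
  Holm–Šidák family-wise error control over the `m = N` node tests;
* a synthetic connectome/cohort generator (modular block topology,
  exponential weights, injectable localized group effects) so every stage
  is testable without imaging data.

## Worked example

```python
import numpy as np
from curvnet import (SyntheticSpec, generate_connectome, curvature_table,
                     global_efficiency, entropy, deletion_cascade, decay_area)

g = generate_connectome(SyntheticSpec(n_nodes=116, seed=42))
table = curvature_table(g)
print(f"edges: {g.n_edges}")
print(f"network average node curvature: {table.network_average:.4f}")
print(f"global efficiency (hop): {global_efficiency(g, 'hop'):.4f}")
print(f"random-walk entropy: {entropy(g):.4f} nats")

ts = deletion_cascade(g, "strength")
tr = deletion_cascade(g, "random", rng=1)
print(f"efficiency decay AUC, strength-targeted: {decay_area(ts, 'global_efficiency'):.2f}")
print(f"efficiency decay AUC, random removal:    {decay_area(tr, 'global_efficiency'):.2f}")
```

prints

```
edges: 1008
network average node curvature: -3.1529
global efficiency (hop): 0.5613
random-walk entropy: 2.4887 nats
efficiency decay AUC, strength-targeted: 40.14
efficiency decay AUC, random removal:    56.81
```

The negative average node curvature reflects the many tree-like edges of a
15%-density network summed over each node's ~17 incident edges; the smaller
area under the strength-targeted decay curve shows that deleting hubs
degrades integration faster than random failure — the targeted-attack
fragility signature.

The same analyses are available from the shell:

```bash
curvnet simulate --out sim/ --n-nodes 116 --seed 42
curvnet curvature --input sim/connectome.tsv --out results/
curvnet robustness --input sim/connectome.tsv --out results/ --measure strength
curvnet compare --group-a dirA/ --group-b dirB/ --measure curvature --alpha 0.05 --out results/
```

Every run writes TSV tables (12 significant digits) and a `manifest.json`
recording the resolved configuration and seed, so runs reproduce
byte-identically.

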