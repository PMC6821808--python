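"""Synthetic connectome and cohort generation.

Emulates the statistical structure of parcellated structural connectivity
matrices well enough to exercise every analysis stage without imaging
data:

* **Weights** are i.i.d. exponential, matching the empirical distribution
  of tractography streamline counts.
* **Topology** is a modular stochastic block model: nodes fall into a few
  communities with a higher edge probability inside than between.  This
  makes curvature, strength and betweenness heterogeneous across nodes
  the way real connectomes are (pure Erdos-Renyi graphs would not).
* **Cohorts** share one edge backbone per cohort, with weights redrawn
  independently per subject — the within-group variance the t-tests need.
  Group differences are injected by scaling (or removing) all edges
  incident to chosen target nodes in group B.

All randomness flows from a single master seed through spawned
``numpy.random.SeedSequence`` streams, so any cohort is reproducible
subject-by-subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort
from .netio import WeightedGraph


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic connectome ensemble.

    Defaults emulate a low-resolution (AAL-like) structural network:
    116 nodes, 15% of possible edges present, exponential weights with
    unit mean, 4 communities with a 4x within/between edge-probability
    ratio.
    """

    n_nodes: int = 116
    density: float = 0.15
    weight_scale: float = 1.0
    n_modules: int = 4
    within_between_ratio: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        n = self.n_nodes
        if self.density * n * (n - 1) / 2 < n - 1:
            warnings.warn(
                "expected edge count below N-1; graph is likely disconnected",
                stacklevel=2,
            )

    def module_of(self) -> np.ndarray:
        """Community assignment: contiguous, near-equal blocks."""
        return (np.arange(self.n_nodes) * self.n_modules) // self.n_nodes


@dataclass
class EffectSpec:
    """Localized group difference injected into group B.

    Every edge incident to a target node has its weight multiplied by
    ``effect_size`` (``weight_scale_down``) or removed outright
    (``edge_removal``).
    """

    target_nodes: list[int] = field(default_factory=list)
    effect_type: str = "weight_scale_down"
    effect_size: float = 0.3

    def __post_init__(self) -> None:
        if self.effect_type not in ("weight_scale_down", "edge_removal"):
            raise ValueError(f"unknown effect_type {self.effect_type!r}")
        if not 0 < self.effect_size < 1:
            raise ValueError("effect_size must lie in (0, 1)")

    def apply(self, w: np.ndarray) -> np.ndarray:
        out = w.copy()
        factor = 0.0 if self.effect_type == "edge_removal" else self.effect_size
        for t in self.target_nodes:
            out[t, :] *= factor
            out[:, t] *= factor
        return out


def _edge_probabilities(spec: SyntheticSpec) -> np.ndarray:
    """Per-pair (upper triangle) edge probability hitting the target density."""
    mod = spec.module_of()
    iu = np.triu_indices(spec.n_nodes, 1)
    within = mod[iu[0]] == mod[iu[1]]
    f_w = within.mean()
    p_between = spec.density / (f_w * spec.within_between_ratio + (1 - f_w))
    p_within = min(spec.within_between_ratio * p_between, 1.0)
    return np.where(within, p_within, p_between)


def _edge_mask(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    probs = _edge_probabilities(spec)
    return rng.random(probs.shape) < probs


def _assemble(spec: SyntheticSpec, mask: np.ndarray, weights: np.ndarray) -> WeightedGraph:
    n = spec.n_nodes
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    vals = np.zeros(mask.shape)
    vals[mask] = weights
    w[iu] = vals
    return WeightedGraph(weights=w + w.T)


def generate_connectome(spec: SyntheticSpec) -> WeightedGraph:
    """One synthetic connectivity matrix, reproducible from ``spec.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    probs = _edge_probabilities(spec)
    mask = rng.random(probs.shape) < probs
    weights = rng.exponential(spec.weight_scale, int(mask.sum()))
    return _assemble(spec, mask, weights)


def generate_cohort(
    spec: SyntheticSpec,
    n_per_group: int,
    effect: EffectSpec | None = None,
    group_names: tuple[str, str] = ("A", "B"),
) -> Cohort:
    """Two groups of subjects sharing one edge backbone.

    The backbone edge set is drawn once from the master seed; each subject
    then draws independent exponential weights on those edges (its own
    spawned stream).  Group B subjects additionally receive the injected
    effect.  With ``effect=None`` the two groups are exchangeable draws
    from the same law.
    """
    master = np.random.SeedSequence(spec.seed)
    backbone_ss, *subject_ss = master.spawn(1 + 2 * n_per_group)
    mask = _edge_mask(spec, np.random.default_rng(backbone_ss))
    n_edges = int(mask.sum())
    subjects, matrices, labels = [], [], []
    for k, ss in enumerate(subject_ss):
        group = group_names[0] if k < n_per_group else group_names[1]
        rng = np.random.default_rng(ss)
        weights = rng.exponential(spec.weight_scale, n_edges)
        g = _assemble(spec, mask, weights)
        if effect is not None and group == group_names[1]:
            g = WeightedGraph(weights=effect.apply(g.weights))
        subjects.append(f"sub-{group}{k % n_per_group:03d}")
        matrices.append(g)
        labels.append(group)
    return Cohort(subjects=subjects, matrices=matrices, group_labels=labels)
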