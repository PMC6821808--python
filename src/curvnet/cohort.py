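"""Group comparison of nodal measures across subject cohorts.

The study design: two groups of subjects, each subject contributing one
connectivity matrix on a shared parcellation.  A nodal measure (curvature,
strength, ...) is computed per subject, an unpaired two-sample t-test with
pooled variance (homoscedasticity assumption) is run at every node, and
the family-wise error rate over the m = number-of-nodes tests is
controlled with the Holm-Sidak step-down procedure at a configured alpha.

Also provided: cross-subject consistency maps (in how many subjects does a
node rank in the top fraction by some measure) and per-subject
cross-measure Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import measures as gm
from .curvature import curvature_table
from .netio import NodeMeasureVector, WeightedGraph

NODAL_MEASURES = (
    "strength",
    "betweenness",
    "clustering",
    "curvature",
    "weighted_curvature",
)


@dataclass
class Cohort:
    """Per-subject connectivity matrices on a shared node set."""

    subjects: list[str]
    matrices: list[WeightedGraph]
    group_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.matrices):
            raise ValueError("one matrix per subject required")
        ids = self.matrices[0].node_ids if self.matrices else []
        for g in self.matrices:
            if g.node_ids != ids:
                raise ValueError("all subjects must share identical node ids")
        if self.group_labels is not None:
            if len(self.group_labels) != len(self.subjects):
                raise ValueError("one group label per subject required")
            if len(set(self.group_labels)) > 2:
                raise ValueError("at most two groups supported")

    @property
    def node_ids(self) -> list[str]:
        return list(self.matrices[0].node_ids)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def split(self) -> tuple["Cohort", "Cohort"]:
        """Split into the two groups, in label-sorted order."""
        labels = sorted(set(self.group_labels))
        parts = []
        for lab in labels:
            idx = [i for i, l in enumerate(self.group_labels) if l == lab]
            parts.append(
                Cohort(
                    subjects=[self.subjects[i] for i in idx],
                    matrices=[self.matrices[i] for i in idx],
                    group_labels=[lab] * len(idx),
                )
            )
        return tuple(parts)


def subject_measure(
    g: WeightedGraph, measure: str, length_mode: str = "inverse_weight"
) -> NodeMeasureVector:
    """One nodal measure for one subject's graph."""
    if measure == "strength":
        return gm.strength(g)
    if measure == "betweenness":
        return gm.betweenness(g, length_mode=length_mode)
    if measure == "clustering":
        return gm.clustering(g)
    if measure in ("curvature", "weighted_curvature"):
        table = curvature_table(g)
        vals = table.node_scalar if measure == "curvature" else table.node_weighted
        return NodeMeasureVector(measure, list(g.node_ids), vals)
    raise ValueError(f"unknown nodal measure {measure!r}")


def cohort_measures(
    cohort: Cohort, measure: str, length_mode: str = "inverse_weight"
) -> np.ndarray:
    """(n_subjects, n_nodes) matrix of one nodal measure across a cohort."""
    return np.vstack(
        [subject_measure(g, measure, length_mode).values for g in cohort.matrices]
    )


@dataclass
class GroupComparison:
    """Per-node two-group test results with family-wise error control."""

    node_ids: list[str]
    mean_a: np.ndarray
    mean_b: np.ndarray
    t_statistic: np.ndarray
    p_value: np.ndarray
    alpha: float
    significant: np.ndarray | None = None
    p_adjusted: np.ndarray | None = None
    zero_variance: np.ndarray | None = None
    measure: str = ""
    group_names: tuple = ("A", "B")

    @property
    def m(self) -> int:
        """Number of tests corrected for: the number of nodes."""
        return len(self.node_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "node_id": self.node_ids,
                "mean_a": self.mean_a,
                "mean_b": self.mean_b,
                "t": self.t_statistic,
                "p": self.p_value,
            }
        )
        if self.p_adjusted is not None:
            df["p_holm_sidak"] = self.p_adjusted
        if self.significant is not None:
            df["significant"] = self.significant
        return df


def ttest_matrix(
    values_a: np.ndarray, values_b: np.ndarray, welch: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise unpaired t-tests between two (subjects x nodes) arrays.

    Default is the pooled-variance (equal variances) test; Welch is opt-in.
    Columns with zero variance in both groups get t = 0, p = 1 and a flag
    rather than a division by zero.
    """
    na, nb = values_a.shape[0], values_b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 subjects")
    ma, mb = values_a.mean(axis=0), values_b.mean(axis=0)
    va, vb = values_a.var(axis=0, ddof=1), values_b.var(axis=0, ddof=1)
    if welch:
        denom = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            np.where(va > 0, (va / na) ** 2 / (na - 1), 0)
            + np.where(vb > 0, (vb / nb) ** 2 / (nb - 1), 0)
            + 1e-300
        )
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = np.full_like(ma, na + nb - 2.0)
    zero = denom == 0
    t = np.zeros_like(ma)
    np.divide(ma - mb, denom, out=t, where=~zero)
    p = np.ones_like(ma)
    p[~zero] = 2.0 * stats.t.sf(np.abs(t[~zero]), df[~zero])
    return t, p, zero


def pernode_ttest(
    cohort: Cohort,
    measure: str = "curvature",
    length_mode: str = "inverse_weight",
    alpha: float = 0.05,
    welch: bool = False,
) -> GroupComparison:
    """Per-node t statistics and raw two-sided p-values (pre-correction)."""
    if cohort.group_labels is None or len(set(cohort.group_labels)) != 2:
        raise ValueError("cohort must carry exactly two group labels")
    a, b = cohort.split()
    va = cohort_measures(a, measure, length_mode)
    vb = cohort_measures(b, measure, length_mode)
    t, p, zero = ttest_matrix(va, vb, welch=welch)
    return GroupComparison(
        node_ids=cohort.node_ids,
        mean_a=va.mean(axis=0),
        mean_b=vb.mean(axis=0),
        t_statistic=t,
        p_value=p,
        alpha=alpha,
        zero_variance=zero,
        measure=measure,
        group_names=(a.group_labels[0], b.group_labels[0]),
    )


def holm_sidak(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Holm-Sidak step-down rejection flags, in the input order.

    Sort the m p-values ascending; the i-th smallest is rejected iff every
    p_(j) with j <= i satisfies p_(j) <= 1 - (1 - alpha)^(1 / (m - j + 1)).
    The rejection set is therefore a down-set of the sorted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    thresholds = 1.0 - (1.0 - alpha) ** (1.0 / (m - ranks + 1))
    ok = p[order] <= thresholds
    passed = np.logical_and.accumulate(ok)
    flags = np.zeros(m, dtype=bool)
    flags[order] = passed
    return flags


def holm_sidak_adjusted(p_values: np.ndarray) -> np.ndarray:
    """Sidak-adjusted step-down p-values, monotonized, in input order."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    adj = 1.0 - (1.0 - p[order]) ** (m - ranks + 1)
    adj = np.maximum.accumulate(adj)
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def compare_groups(
    cohort: Cohort,
    measure: str = "curvature",
    alpha: float = 0.05,
    length_mode: str = "inverse_weight",
    welch: bool = False,
) -> GroupComparison:
    """Full two-group nodal comparison with Holm-Sidak FWER control."""
    cmp = pernode_ttest(
        cohort, measure=measure, length_mode=length_mode, alpha=alpha, welch=welch
    )
    cmp.significant = holm_sidak(cmp.p_value, alpha)
    cmp.p_adjusted = holm_sidak_adjusted(cmp.p_value)
    return cmp


def consistency_map(
    cohort: Cohort,
    measure: str = "curvature",
    top_fraction: float = 0.25,
    length_mode: str = "inverse_weight",
    values: np.ndarray | None = None,
) -> NodeMeasureVector:
    """Count, per node, the subjects in which it ranks in the top fraction.

    Each subject marks its top ceil(top_fraction * N) nodes by the measure
    (ties at the cutoff resolved toward the lower node index); the map is
    the per-node count of marking subjects.  Precomputed per-subject
    values may be passed to avoid recomputation.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    vals = values if values is not None else cohort_measures(cohort, measure, length_mode)
    n = vals.shape[1]
    k = int(np.ceil(top_fraction * n))
    counts = np.zeros(n, dtype=float)
    for row in vals:
        order = sorted(range(n), key=lambda i: (-row[i], i))
        counts[order[:k]] += 1
    return NodeMeasureVector(f"top{top_fraction:g}_count", cohort.node_ids, counts)


def measure_correlation_histogram(
    cohort: Cohort,
    measure_a: str,
    measure_b: str,
    length_mode: str = "inverse_weight",
    values_a: np.ndarray | None = None,
    values_b: np.ndarray | None = None,
) -> dict:
    """Per-subject Pearson r between two nodal measures, plus summaries.

    Subjects in which either measure is constant (correlation undefined)
    are skipped and reported.
    """
    va = values_a if values_a is not None else cohort_measures(cohort, measure_a, length_mode)
    vb = values_b if values_b is not None else cohort_measures(cohort, measure_b, length_mode)
    rs, skipped = [], []
    for subj, a, b in zip(cohort.subjects, va, vb):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            skipped.append(subj)
            continue
        rs.append(float(stats.pearsonr(a, b).statistic))
    rs = np.array(rs)
    return {
        "subjects": [s for s in cohort.subjects if s not in skipped],
        "r": rs,
        "mean": float(rs.mean()) if rs.size else np.nan,
        "variance": float(rs.var(ddof=0)) if rs.size else np.nan,
        "skipped": skipped,
    }
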