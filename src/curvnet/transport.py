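"""Wasserstein-1 (earth mover's) distance between discrete measures.

The distance between measures p and q on a finite metric space with
pairwise costs c_ij is the optimum of the transportation linear program

    W1(p, q) = min_{pi >= 0} sum_ij c_ij pi_ij
               s.t.  sum_j pi_ij = p_i,   sum_i pi_ij = q_j.

:func:`emd` solves it exactly with the HiGHS LP solver; the value contract
is the optimum to 1e-9, not a particular optimal vertex (the minimizing
plan need not be unique).  :func:`emd_bruteforce` is a deliberately naive
exhaustive enumeration over integer plans, kept independent of the LP path
so it can serve as an oracle in tests.

Costs are always passed in explicitly (for graph neighbourhood measures
they are hop distances computed by :mod:`curvnet.netio`); this module never
recomputes graph distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import coo_matrix

_MASS_TOL = 1e-12
_FEAS_TOL = 1e-9


class TransportError(ValueError):
    pass


@dataclass
class DiscreteMeasure:
    """Probability mass assignment over an ordered set of node ids."""

    support: list
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if len(self.support) != self.masses.shape[0]:
            raise TransportError("support/mass length mismatch")
        if len(set(self.support)) != len(self.support):
            raise TransportError("support ids must be unique")
        if (self.masses < 0).any():
            raise TransportError("negative mass")
        if abs(self.masses.sum() - 1.0) > 1e-9:
            raise TransportError(
                f"masses sum to {self.masses.sum():.12g}, expected 1"
            )

    def without_zeros(self) -> "DiscreteMeasure":
        """Drop zero-mass support points (keeps the LP nondegenerate)."""
        keep = self.masses > _MASS_TOL
        if keep.all():
            return self
        return DiscreteMeasure(
            support=[s for s, k in zip(self.support, keep) if k],
            masses=self.masses[keep] / self.masses[keep].sum(),
        )


@dataclass
class TransportPlan:
    """Feasible coupling pi with marginals p (rows) and q (columns)."""

    rows: list
    cols: list
    plan: np.ndarray
    cost: float

    def check_feasible(self, p: np.ndarray, q: np.ndarray, tol: float = _FEAS_TOL):
        assert (self.plan >= -tol).all(), "negative plan entry"
        assert np.allclose(self.plan.sum(axis=1), p, atol=tol), "row marginal"
        assert np.allclose(self.plan.sum(axis=0), q, atol=tol), "column marginal"


def _solve_lp(p: np.ndarray, q: np.ndarray, cost: np.ndarray) -> tuple[float, np.ndarray]:
    n, m = cost.shape
    # Equality constraints: n row-sum + m column-sum rows; one is redundant
    # (total mass), which HiGHS handles without trouble.  Each variable
    # pi_ij appears in exactly two constraints, so the matrix is built
    # sparse (COO) directly.
    var = np.arange(n * m)
    rows = np.concatenate([var // m, n + var % m])
    cols = np.concatenate([var, var])
    a_eq = coo_matrix(
        (np.ones(2 * n * m), (rows, cols)), shape=(n + m, n * m)
    )
    b_eq = np.concatenate([p, q])
    res = linprog(cost.ravel(), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise TransportError(f"transport LP failed: {res.message}")
    return float(res.fun), res.x.reshape(n, m)


def emd(
    p: DiscreteMeasure,
    q: DiscreteMeasure,
    cost: np.ndarray,
    assume_metric: bool = False,
) -> tuple[float, TransportPlan]:
    """Exact earth mover's distance and an optimal transport plan.

    Parameters
    ----------
    p, q
        Discrete probability measures; ``cost[i, j]`` is the distance from
        ``p.support[i]`` to ``q.support[j]``.  Must be finite, nonnegative.
    assume_metric
        If true, the caller certifies that the cost is a metric restricted
        to the two supports: zero between identically-labelled support
        points and satisfying the triangle inequality.  Mass common to
        both measures (matched by support id) is then held in place at
        zero cost — exact for metric costs — and only the residual
        measures enter the LP — a large saving when supports overlap, as they do
        for neighbourhood measures of adjacent nodes.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.shape != (len(p.support), len(q.support)):
        raise TransportError(
            f"cost shape {cost.shape} does not match supports "
            f"({len(p.support)}, {len(q.support)})"
        )
    if not np.isfinite(cost).all():
        raise TransportError("infinite or NaN cost entry")
    if (cost < 0).any():
        raise TransportError("negative cost entry")

    if assume_metric:
        return _emd_metric_reduced(p, q, cost)

    p0, q0 = p.without_zeros(), q.without_zeros()
    ri = [p.support.index(s) for s in p0.support]
    ci = [q.support.index(s) for s in q0.support]
    val, sub = _solve_lp(p0.masses, q0.masses, cost[np.ix_(ri, ci)])
    full = np.zeros((len(p.support), len(q.support)))
    full[np.ix_(ri, ci)] = sub
    plan = TransportPlan(rows=list(p.support), cols=list(q.support), plan=full, cost=val)
    plan.check_feasible(p.masses, q.masses)
    return val, plan


def _emd_metric_reduced(p, q, cost):
    """EMD with the shared-mass reduction (cost must be a metric)."""
    np_, nq = len(p.support), len(q.support)
    pos_q = {s: j for j, s in enumerate(q.support)}
    shared = [(i, pos_q[s]) for i, s in enumerate(p.support) if s in pos_q]
    stay = np.zeros((np_, nq))
    pr, qr = p.masses.copy(), q.masses.copy()
    for i, j in shared:
        keep = min(pr[i], qr[j])
        stay[i, j] = keep
        pr[i] -= keep
        qr[j] -= keep
    rem = pr.sum()
    if rem <= _MASS_TOL:  # measures identical up to tolerance
        plan = TransportPlan(rows=list(p.support), cols=list(q.support),
                             plan=stay, cost=0.0)
        plan.check_feasible(p.masses, q.masses)
        return 0.0, plan
    ri = np.flatnonzero(pr > _MASS_TOL)
    ci = np.flatnonzero(qr > _MASS_TOL)
    val, sub = _solve_lp(pr[ri] / rem, qr[ci] / rem, cost[np.ix_(ri, ci)])
    val *= rem
    full = stay
    full[np.ix_(ri, ci)] += sub * rem
    plan = TransportPlan(rows=list(p.support), cols=list(q.support), plan=full, cost=val)
    plan.check_feasible(p.masses, q.masses)
    return val, plan


_MAX_BRUTE_SUPPORT = 4


def emd_bruteforce(
    p: DiscreteMeasure,
    q: DiscreteMeasure,
    cost: np.ndarray,
    resolution: int,
) -> float:
    """Exhaustive EMD over integer transport plans in units of 1/resolution.

    All plans with integer entries whose row sums are ``p * resolution``
    and column sums ``q * resolution`` are enumerated recursively; for a
    resolution that is a common denominator of the masses this equals the
    LP optimum exactly.  Supports are limited to 4 points to guard against
    combinatorial blow-up.
    """
    if len(p.support) > _MAX_BRUTE_SUPPORT or len(q.support) > _MAX_BRUTE_SUPPORT:
        raise TransportError("brute-force oracle limited to supports of size <= 4")
    cost = np.asarray(cost, dtype=float)
    pL = np.rint(p.masses * resolution).astype(int)
    qL = np.rint(q.masses * resolution).astype(int)
    if pL.sum() != resolution or qL.sum() != resolution:
        raise TransportError("masses are not multiples of 1/resolution")

    n, m = len(pL), len(qL)
    best = [np.inf]

    def recurse(i: int, remaining_cols: np.ndarray, acc: float) -> None:
        if acc >= best[0]:
            return
        if i == n:
            if not remaining_cols.any():
                best[0] = acc
            return
        # enumerate all splits of row i's mass across the m columns
        def split(j: int, left: int, cols: np.ndarray, c: float) -> None:
            if c >= best[0]:
                return
            if j == m - 1:
                if left <= cols[j]:
                    cols2 = cols.copy()
                    cols2[j] -= left
                    recurse(i + 1, cols2, c + cost[i, j] * left)
                return
            for t in range(min(left, cols[j]) + 1):
                cols2 = cols.copy()
                cols2[j] -= t
                split(j + 1, left - t, cols2, c + cost[i, j] * t)

        split(0, int(pL[i]), remaining_cols, acc)

    recurse(0, qL.copy(), 0.0)
    return best[0] / resolution
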