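import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from curvnet.cohort import (
    Cohort,
    compare_groups,
    consistency_map,
    holm_sidak,
    holm_sidak_adjusted,
    measure_correlation_histogram,
    pernode_ttest,
    ttest_matrix,
)
from curvnet.synth import SyntheticSpec, generate_cohort

from conftest import random_weighted_graph


def small_cohort(rng, n_per_group=3, n_nodes=8):
    mats = [random_weighted_graph(n_nodes, 0.5, rng) for _ in range(2 * n_per_group)]
    # identical node ids across subjects by construction (default n0..n{N-1})
    return Cohort(
        subjects=[f"s{i}" for i in range(2 * n_per_group)],
        matrices=mats,
        group_labels=["A"] * n_per_group + ["B"] * n_per_group,
    )


class TestTTest:
    def test_identical_groups_p_one(self):
        vals = np.tile([[1.0, 2.0, 3.0]], (3, 1))
        t, p, zero = ttest_matrix(vals, vals.copy())
        np.testing.assert_array_equal(t, 0.0)
        np.testing.assert_array_equal(p, 1.0)
        assert zero.all()

    def test_zero_within_group_variance_flagged(self):
        a = np.zeros((3, 1))
        b = np.ones((3, 1))
        t, p, zero = ttest_matrix(a, b)
        assert zero[0] and p[0] == 1.0

    def test_closed_form_pooled_t(self):
        a = np.array([[1.0], [2], [3], [4]])
        b = np.array([[3.0], [4], [5], [6]])
        t, p, _ = ttest_matrix(a, b)
        assert t[0] == pytest.approx(-2.1909, abs=1e-4)
        assert p[0] == pytest.approx(0.0709, abs=1e-4)

    def test_matches_scipy(self, rng):
        from scipy.stats import ttest_ind

        a, b = rng.normal(size=(5, 20)), rng.normal(size=(7, 20))
        t, p, _ = ttest_matrix(a, b)
        ref = ttest_ind(a, b, axis=0, equal_var=True)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-12)
        np.testing.assert_allclose(p, ref.pvalue, atol=1e-12)

    def test_pernode_requires_two_groups(self, rng):
        c = small_cohort(rng)
        c.group_labels = ["A"] * 6
        with pytest.raises(ValueError):
            pernode_ttest(c, measure="strength")


class TestHolmSidak:
    def test_single_test_plain_alpha(self):
        assert holm_sidak(np.array([0.04]), alpha=0.05)[0]
        assert not holm_sidak(np.array([0.06]), alpha=0.05)[0]

    def test_all_rejected_example(self):
        # step-down thresholds for m=3 at alpha=0.05:
        # 0.016952, 0.025321, 0.05
        flags = holm_sidak(np.array([0.01, 0.02, 0.04]), alpha=0.05)
        assert flags.all()

    def test_none_rejected_example(self):
        flags = holm_sidak(np.array([0.2, 0.3, 0.9]), alpha=0.05)
        assert not flags.any()

    def test_step_down_stops(self):
        # smallest p fails its threshold, so nothing is rejected even
        # though 0.04 alone would pass the last threshold
        flags = holm_sidak(np.array([0.03, 0.04, 0.9]), alpha=0.05)
        assert not flags.any()

    def test_rejections_form_down_set(self, rng):
        p = rng.uniform(0, 0.2, 50)
        flags = holm_sidak(p, alpha=0.05)
        if flags.any():
            assert p[flags].max() <= p[~flags].min() + 1e-15

    def test_superset_of_holm_bonferroni(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 0.1, 30)
            hs = holm_sidak(p, alpha=0.05)
            hb = multipletests(p, alpha=0.05, method="holm")[0]
            assert (hs | ~hb).all()  # hb rejected => hs rejected

    def test_matches_statsmodels_decisions(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 0.15, 40)
            hs = holm_sidak(p, alpha=0.05)
            ref = multipletests(p, alpha=0.05, method="holm-sidak")[0]
            np.testing.assert_array_equal(hs, ref)

    def test_adjusted_pvalues_monotone(self, rng):
        p = rng.uniform(0, 1, 25)
        adj = holm_sidak_adjusted(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert ((adj >= p - 1e-15) & (adj <= 1.0)).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            holm_sidak(np.array([1.5]), alpha=0.05)
        with pytest.raises(ValueError):
            holm_sidak(np.array([0.5]), alpha=1.0)


class TestConsistencyMap:
    def test_identical_subjects_all_or_nothing(self, rng):
        g = random_weighted_graph(8, 0.5, rng)
        c = Cohort(subjects=["a", "b", "c"], matrices=[g, g, g])
        counts = consistency_map(c, "strength", 0.25).values
        assert set(counts.tolist()) <= {0.0, 3.0}

    def test_single_subject_ceiling(self, rng):
        g = random_weighted_graph(4, 0.9, rng)
        c = Cohort(subjects=["a"], matrices=[g])
        counts = consistency_map(c, "strength", 0.25).values
        assert counts.sum() == 1  # ceil(0.25 * 4)

    def test_counts_bounded_and_sum(self, rng):
        c = small_cohort(rng, n_per_group=3, n_nodes=10)
        counts = consistency_map(c, "strength", 0.25).values
        k = int(np.ceil(0.25 * 10))
        assert counts.max() <= 6
        assert counts.sum() == 6 * k

    def test_disjoint_tops_count_one(self):
        # three subjects whose top node (by strength) is a different node
        mats = []
        for hot in range(3):
            w = np.zeros((4, 4))
            others = [x for x in range(4) if x != hot]
            # hot node strictly strongest: two incident weight-10 edges
            w[hot, others[0]] = w[others[0], hot] = 10.0
            w[hot, others[1]] = w[others[1], hot] = 10.0
            mats.append(random_graph_from(w))
        c = Cohort(subjects=list("abc"), matrices=mats)
        counts = consistency_map(c, "strength", 0.25).values
        assert counts.max() == 1.0

    def test_fraction_bounds(self, rng):
        c = small_cohort(rng)
        with pytest.raises(ValueError):
            consistency_map(c, "strength", 1.0)


def random_graph_from(w):
    from curvnet.netio import WeightedGraph

    return WeightedGraph(weights=w)


class TestMeasureCorrelation:
    def test_same_measure_r_one(self, rng):
        c = small_cohort(rng)
        out = measure_correlation_histogram(c, "strength", "strength")
        np.testing.assert_allclose(out["r"], 1.0)
        assert out["variance"] == pytest.approx(0.0)

    def test_single_subject(self, rng):
        g = random_weighted_graph(8, 0.5, rng)
        c = Cohort(subjects=["a"], matrices=[g])
        out = measure_correlation_histogram(c, "strength", "clustering")
        assert out["variance"] == 0.0 and len(out["r"]) == 1

    def test_constant_subject_skipped(self, rng):
        from conftest import complete_graph

        c = Cohort(
            subjects=["a", "b"],
            matrices=[complete_graph(6), random_weighted_graph(6, 0.5, rng)],
        )
        out = measure_correlation_histogram(c, "strength", "clustering")
        assert "a" in out["skipped"]

    def test_independent_measures_near_zero(self, rng):
        """Null sampling distribution: uncorrelated random measures."""
        n_subj, n_nodes = 30, 50
        va = rng.normal(size=(n_subj, n_nodes))
        vb = rng.normal(size=(n_subj, n_nodes))
        g = random_weighted_graph(n_nodes, 0.3, rng)
        c = Cohort(subjects=[f"s{i}" for i in range(n_subj)], matrices=[g] * n_subj)
        out = measure_correlation_histogram(c, "x", "y", values_a=va, values_b=vb)
        assert abs(out["mean"]) < 0.1


class TestEndToEnd:
    def test_effect_recovered(self):
        targets = [2, 9, 17, 25, 33]
        from curvnet.synth import EffectSpec

        coh = generate_cohort(
            SyntheticSpec(n_nodes=40, density=0.3, seed=11),
            n_per_group=10,
            effect=EffectSpec(target_nodes=targets, effect_size=0.3),
        )
        cmp = compare_groups(coh, measure="strength")
        assert set(np.flatnonzero(cmp.significant)) >= set(targets) - {targets[0]}
        assert cmp.m == 40

    def test_curvature_group_difference_detectable(self):
        """Removing edges at target nodes shifts their curvature enough for
        the corrected test to find them on a small cohort."""
        from curvnet.synth import EffectSpec

        targets = [5, 12, 20]
        coh = generate_cohort(
            SyntheticSpec(n_nodes=30, density=0.35, seed=4),
            n_per_group=8,
            effect=EffectSpec(target_nodes=targets, effect_type="edge_removal",
                              effect_size=0.5),
        )
        cmp = compare_groups(coh, measure="curvature")
        assert cmp.significant[targets].sum() >= 2

    def test_null_cohort_rarely_rejects(self):
        rejections = 0
        for seed in range(10):
            coh = generate_cohort(
                SyntheticSpec(n_nodes=50, density=0.25, seed=300 + seed), n_per_group=8
            )
            cmp = compare_groups(coh, measure="strength")
            rejections += int(cmp.significant.any())
        assert rejections <= 2
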