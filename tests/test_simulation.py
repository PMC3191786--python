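"""Synthetic benchmark generator, variance ratios, Wilcoxon test."""

import numpy as np
import pytest
import scipy.stats

from multicsp.simulation import (
    A1_DEFAULT,
    A2_DEFAULT,
    SimulationConfig,
    generate_benchmark,
    run_toy_comparison,
    sample_mixing,
    task_cov_pair,
    variance_ratios,
    wilcoxon_signed_rank,
)


class TestSampleMixing:
    def test_zero_variance_copies_cluster_means(self, rng):
        np.testing.assert_array_equal(
            sample_mixing(A1_DEFAULT, 0.0, rng), A1_DEFAULT
        )
        np.testing.assert_array_equal(
            sample_mixing(A2_DEFAULT, 0.0, rng), A2_DEFAULT
        )

    def test_perturbation_variance_is_calibrated(self, rng):
        var = 1e-4
        draws = np.stack(
            [sample_mixing(A1_DEFAULT, var, rng) - A1_DEFAULT for _ in range(10_000)]
        )
        sample_var = draws.reshape(10_000, -1).var(axis=0)
        np.testing.assert_allclose(sample_var, var, rtol=0.1)


class TestGenerateBenchmark:
    def test_default_counts(self):
        tasks = generate_benchmark(SimulationConfig(seed=0))
        assert len(tasks) == 40
        assert sum(t.cluster_id == 1 for t in tasks) == 20
        for t in tasks:
            for c in (1, 2):
                assert t.train[c].shape == (15, 2)
                assert t.test[c].shape == (285, 2)

    def test_deterministic_under_seed(self):
        a = generate_benchmark(SimulationConfig(seed=11))
        b = generate_benchmark(SimulationConfig(seed=11))
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.mixing, tb.mixing)
            np.testing.assert_array_equal(ta.train[1], tb.train[1])
            np.testing.assert_array_equal(ta.test[2], tb.test[2])

    def test_earlier_tasks_stable_when_more_added(self):
        small = generate_benchmark(SimulationConfig(seed=4, tasks_per_cluster=3))
        # cluster-2 tasks move, but the first cluster-1 tasks are untouched
        big = generate_benchmark(SimulationConfig(seed=4, tasks_per_cluster=5))
        np.testing.assert_array_equal(small[0].train[1], big[0].train[1])
        np.testing.assert_array_equal(small[2].test[2], big[2].test[2])

    def test_unmixed_test_points_recover_source_covariance(self):
        cfg = SimulationConfig(seed=2, n_test_per_condition=5000)
        task = generate_benchmark(cfg)[0]
        inv = np.linalg.inv(task.mixing)
        for c, target in ((1, np.diag([5.0, 1.0])), (2, np.diag([1.0, 5.0]))):
            unmixed = task.test[c] @ inv.T
            cov = unmixed.T @ unmixed / unmixed.shape[0]
            np.testing.assert_allclose(cov, target, atol=0.35)

    def test_pooled_source_variance_within_three_standard_errors(self):
        cfg = SimulationConfig(seed=9)
        tasks = generate_benchmark(cfg)
        for c, target in ((1, np.array([5.0, 1.0])), (2, np.array([1.0, 5.0]))):
            pooled = np.vstack([t.test[c] @ np.linalg.inv(t.mixing).T for t in tasks])
            n = pooled.shape[0]
            var = pooled.var(axis=0)
            se = target * np.sqrt(2.0 / n)  # SE of a chi-square variance
            assert np.all(np.abs(var - target) < 3.05 * se + 2e-3)

    def test_mixing_construction(self):
        task = generate_benchmark(SimulationConfig(seed=0))[25]
        assert task.cluster_id == 2
        np.testing.assert_allclose(task.mixing, A2_DEFAULT, atol=0.05)


class TestVarianceRatios:
    def test_equal_condition_covariances_give_unit_ratios(self, rng):
        pts = rng.standard_normal((500, 2))
        task = generate_benchmark(SimulationConfig(seed=0))[0]
        task.test = {1: pts, 2: pts}
        ratios = variance_ratios([np.array([1.0, 0.0]), np.array([0.0, 1.0])], task)
        np.testing.assert_allclose(ratios, [1.0, 1.0])

    def test_perfect_unmixing_approaches_five(self):
        cfg = SimulationConfig(seed=6, n_test_per_condition=20000, noise_var=1e-8)
        task = generate_benchmark(cfg)[0]
        inv = np.linalg.inv(task.mixing)
        ratios = variance_ratios([inv[0], inv[1]], task)
        np.testing.assert_allclose(ratios, [5.0, 5.0], rtol=0.1)

    def test_invariant_to_filter_rescaling(self, rng):
        task = generate_benchmark(SimulationConfig(seed=1))[3]
        w1, w2 = rng.standard_normal(2), rng.standard_normal(2)
        a = variance_ratios([w1, w2], task)
        b = variance_ratios([-3.0 * w1, 0.2 * w2], task)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_sorted_descending(self, rng):
        task = generate_benchmark(SimulationConfig(seed=1))[0]
        r = variance_ratios([rng.standard_normal(2), rng.standard_normal(2)], task)
        assert r[0] >= r[1]


class TestWilcoxon:
    def test_all_positive_n5_exact(self):
        d = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        w, p = wilcoxon_signed_rank(d, alternative="greater")
        assert w == 15.0
        assert p == pytest.approx(1.0 / 32.0)
        _, p2 = wilcoxon_signed_rank(d)
        assert p2 == pytest.approx(2.0 / 32.0)

    def test_antisymmetric_sample_is_null_centered(self):
        d = np.array([-1.0, 1.5, -1.5, 1.0, 2.0, -2.0])
        w, p = wilcoxon_signed_rank(d)
        assert w == pytest.approx(6 * 7 / 4.0)  # statistic at the null mean
        assert p == 1.0

    def test_zeros_dropped(self):
        d = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.0])
        w, _ = wilcoxon_signed_rank(d)
        assert w == 15.0

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.zeros(6))

    def test_agreement_with_reference_exact(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 26))
            d = rng.standard_normal(n)
            _, p = wilcoxon_signed_rank(d)
            ref = scipy.stats.wilcoxon(d, method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_agreement_with_reference_normal_approximation(self, rng):
        for _ in range(50):
            n = int(rng.integers(26, 80))
            d = rng.standard_normal(n)
            _, p = wilcoxon_signed_rank(d)
            ref = scipy.stats.wilcoxon(d, method="approx", correction=False)
            assert p == pytest.approx(ref.pvalue, abs=1e-6)


class TestToyComparison:
    def test_smoke_single_replicate(self):
        cfg = SimulationConfig(seed=1)
        res = run_toy_comparison(cfg)
        assert res.table.shape[0] == 4  # 2 clusters x 2 sources
        assert set(res.table.columns) >= {"median_bcsp", "median_clmtcsp",
                                          "wilcoxon_p"}
        assert res.ratios_bcsp.shape == (40, 2)
        assert (res.ratios_bcsp[:, 0] >= res.ratios_bcsp[:, 1]).all()
        assert 0.0 <= res.assignment_accuracy <= 1.0
        assert "cluster recovery" in res.summary()

    def test_degenerate_limit_both_methods_near_perfect(self):
        # no mixing spread and no noise: both methods unmix essentially
        # perfectly and the gap between them vanishes
        cfg = SimulationConfig(seed=8, mixing_column_var=0.0, noise_var=1e-12,
                               n_train_per_condition=200,
                               n_test_per_condition=200,
                               tasks_per_cluster=8)
        res = run_toy_comparison(cfg)
        assert (res.table.median_bcsp > 4.0).all()
        assert (res.table.median_clmtcsp > 4.0).all()
        gap = np.abs(res.table.median_clmtcsp - res.table.median_bcsp)
        assert (gap < 0.25).all()
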