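"""Generator: network prior, tree-generating process, noise, metrics."""

import numpy as np
import pytest

from treemhn import (
    MHN,
    MutationTree,
    NoiseConfig,
    ThetaPrior,
    edge_recovery_metrics,
    perturb_tree,
    random_theta,
    sample_cohort,
    sample_tree,
    tree_probability,
)

from conftest import LOG_HALF


class TestRandomTheta:
    def test_diagonals_in_prior_range(self):
        m = random_theta(ThetaPrior(n=20), seed=0)
        d = m.theta.diagonal()
        assert np.all((d >= -6.0) & (d <= -1.0))

    def test_full_sparsity_gives_diagonal_network(self):
        m = random_theta(ThetaPrior(n=6, sparsity=1.0), seed=1)
        off = ~np.eye(6, dtype=bool)
        assert np.all(m.theta[off] == 0.0)

    def test_offdiagonal_law_of_large_numbers(self):
        # pool many draws: half negative, mean magnitude alpha/beta = 1.6
        m = random_theta(ThetaPrior(n=120, sparsity=0.0), seed=2)
        off = m.theta[~np.eye(120, dtype=bool)]
        frac_neg = np.mean(off < 0)
        assert abs(frac_neg - 0.5) < 3 * 0.5 / np.sqrt(off.size)
        mags = np.abs(off)
        se = mags.std() / np.sqrt(off.size)
        assert abs(mags.mean() - 1.6) < 3 * se

    def test_deterministic_given_seed(self):
        a = random_theta(ThetaPrior(n=5), seed=7)
        b = random_theta(ThetaPrior(n=5), seed=7)
        assert np.array_equal(a.theta, b.theta)


class TestSampleTree:
    def test_root_only_fraction(self):
        m = MHN(theta=np.array([[LOG_HALF]]))
        n_samples = 30_000
        rng = np.random.default_rng(0)
        hits = sum(sample_tree(m, rng).size == 0 for _ in range(n_samples))
        p = 1.0 / 1.5
        se = np.sqrt(p * (1 - p) / n_samples)
        assert abs(hits / n_samples - p) < 3 * se

    def test_frequency_matches_exact_probability(self, diag_half_n2):
        target = MutationTree.from_paths(2, [(), (1,)])
        p = tree_probability(diag_half_n2, target)  # 0.125
        n_samples = 30_000
        rng = np.random.default_rng(1)
        hits = sum(
            sample_tree(diag_half_n2, rng).paths == target.paths
            for _ in range(n_samples)
        )
        se = np.sqrt(p * (1 - p) / n_samples)
        assert abs(hits / n_samples - p) < 3 * se

    def test_empirical_distribution_goodness_of_fit(self, diag_half_n2):
        """Observed tree frequencies match the exact likelihood (chi-square)."""
        from collections import Counter
        from scipy.stats import chisquare

        from treemhn.enumeration import enumerate_all_trees

        n_samples = 20_000
        rng = np.random.default_rng(2)
        counts = Counter(
            sample_tree(diag_half_n2, rng).canonical() for _ in range(n_samples)
        )
        trees = enumerate_all_trees(2)
        expected = np.array([tree_probability(diag_half_n2, t) for t in trees])
        observed = np.array([counts.get(t.canonical(), 0) for t in trees])
        stat, pval = chisquare(observed, expected * n_samples)
        assert pval > 0.001

    def test_generated_trees_are_valid(self):
        truth = random_theta(ThetaPrior(n=6), seed=3)
        for t in sample_cohort(truth, 50, seed=4):
            assert () in t.paths  # construction already validated


class TestPerturbTree:
    def test_zero_epsilon_is_identity(self):
        t = MutationTree.from_paths(3, [(), (1,), (1, 2)])
        assert perturb_tree(t, NoiseConfig(0.0), seed=0) is t

    def test_full_relabel_changes_labels(self):
        t = MutationTree.from_paths(10, [(), (1,), (2,)])
        out = perturb_tree(t, NoiseConfig(1.0, kind="relabel"), seed=0)
        assert out.paths != t.paths
        assert out.size == t.size

    def test_outputs_always_valid(self):
        # construction of MutationTree revalidates; survive many random trials
        truth = random_theta(ThetaPrior(n=5), seed=5)
        trees = sample_cohort(truth, 100, seed=6)
        rng = np.random.default_rng(7)
        for t in trees:
            for kind in ("relabel", "prune_reattach", "mixed"):
                out = perturb_tree(t, NoiseConfig(0.5, kind=kind), rng)
                assert out.n == t.n

    def test_deterministic_given_seed(self):
        t = MutationTree.from_paths(6, [(), (1,), (1, 2), (3,)])
        a = perturb_tree(t, NoiseConfig(0.8), seed=11)
        b = perturb_tree(t, NoiseConfig(0.8), seed=11)
        assert a.paths == b.paths


class TestEdgeRecoveryMetrics:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.truth = random_theta(ThetaPrior(n=5), rng).theta

    def test_perfect_estimate(self):
        p, r = edge_recovery_metrics(self.truth, self.truth)
        assert (p, r) == (1.0, 1.0)

    def test_all_zero_estimate(self):
        hat = np.diag(self.truth.diagonal())
        p, r = edge_recovery_metrics(self.truth, hat)
        assert p is None and r == 0.0

    def test_sign_flip_has_zero_precision(self):
        hat = -self.truth.copy()
        hat[np.diag_indices(5)] = self.truth.diagonal()
        p, _ = edge_recovery_metrics(self.truth, hat)
        assert p == 0.0

    def test_top_fraction_restricts_to_high_baseline_mutations(self):
        hat = self.truth.copy()
        low = np.argsort(-self.truth.diagonal())[3:]  # outside the top half of 5
        hat[low[0], low[1]] = -hat[low[0], low[1]] if hat[low[0], low[1]] else 1.0
        p_full, _ = edge_recovery_metrics(self.truth, hat, 1.0)
        p_top, _ = edge_recovery_metrics(self.truth, hat, 0.5)
        assert p_top == 1.0
        assert p_full < 1.0


class TestBenchmarkRun:
    def test_reproducible_and_sane(self):
        from treemhn import BenchmarkConfig, benchmark_run

        cfg = BenchmarkConfig(
            n_mutations=(4,), n_trees=(60,), gammas=(0.5,), repetitions=2, seed=3
        )
        a = benchmark_run(cfg)
        b = benchmark_run(cfg)
        assert a.equals(b)
        assert len(a) == 2
        assert (a["kl_truth_vs_estimate"] >= 0).all()
        assert (a["kl_estimate_vs_truth"] >= 0).all()

    def test_noise_level_flows_through(self):
        from treemhn import BenchmarkConfig, benchmark_run

        cfg = BenchmarkConfig(
            n_mutations=(4,), n_trees=(40,), gammas=(0.5,), repetitions=1,
            epsilon=0.1, seed=4,
        )
        out = benchmark_run(cfg)
        assert (out["epsilon"] == 0.1).all()
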