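"""Estimation: E-steps, M-step stationarity, MLE/EM agreement, dispatch."""

import numpy as np
import pytest

from treemhn import (
    FitConfig,
    MHN,
    MutationTree,
    estep_exact,
    estep_mc,
    fit,
    fit_em,
    fit_mle,
    mstep,
    sample_cohort,
    random_theta,
    ThetaPrior,
)

from conftest import random_mhn, random_small_tree


class TestEStepExact:
    def test_unobserved_event_root_only_closed_form(self):
        # p = lam_s / (lam_s + lam); E[Z] = 1/lam - (1/p) dp/dlam = 1/lam + 1/(lam_s+lam)
        m = MHN(theta=np.array([[0.0]]))  # lam = 1
        t = MutationTree.from_paths(1, [()])
        gaps = estep_exact(m, t)
        assert gaps[((), 1)] == pytest.approx(1.5, abs=1e-10)

    def test_observed_gaps_below_unconditional_mean(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = int(rng.integers(2, 4))
            m = random_mhn(n, rng)
            t = random_small_tree(n, rng)
            gaps = estep_exact(m, t)
            for (p, i), z in gaps.items():
                assert z > 0
                if p + (i,) in t.paths:  # truncation below the sampling time
                    assert z <= 1.0 / m.rate(p, i) + 1e-10
                else:  # truncation above it
                    assert z >= 1.0 / m.rate(p, i) - 1e-10


class TestEStepMonteCarlo:
    def test_truncated_exponential_marginal_mean(self):
        from treemhn.estimation import _sample_texp

        rng = np.random.default_rng(0)
        lam, b, n = 2.0, 1.0, 100_000
        z = _sample_texp(rng, np.full(n, lam), np.full(n, b))
        expected = 1.0 / lam - b * np.exp(-lam * b) / (1.0 - np.exp(-lam * b))
        se = z.std() / np.sqrt(n)
        assert abs(z.mean() - expected) < 3 * se
        assert z.max() <= b

    def test_agrees_with_exact(self):
        rng = np.random.default_rng(11)
        m = random_mhn(2, rng)
        t = MutationTree.from_paths(2, [(), (1,)])
        exact = estep_exact(m, t)
        mc = estep_mc(m, t, n_samples=40_000, seed=5)
        for k in exact:
            assert mc[k] == pytest.approx(exact[k], rel=0.05)

    def test_deterministic_given_seed(self):
        m = MHN(theta=np.diag([-1.0, -0.5]))
        t = MutationTree.from_paths(2, [(), (2,)])
        a = estep_mc(m, t, n_samples=500, seed=9)
        b = estep_mc(m, t, n_samples=500, seed=9)
        assert a == b


class TestMStep:
    def test_exponential_rate_stationarity(self):
        # one tree, one event: maximizer of theta - e^theta * E[Z] is 1/E[Z]
        t = MutationTree.from_paths(1, [()])
        gaps = [{((), 1): 2.0}]
        theta = mstep(gaps, [t], gamma=1e-9)
        assert np.exp(theta[0, 0]) == pytest.approx(0.5, rel=1e-4)

    def test_large_gamma_zeroes_off_diagonals(self):
        rng = np.random.default_rng(1)
        m = random_mhn(2, rng)
        trees = [
            MutationTree.from_paths(2, [(), (1,), (1, 2)]),
            MutationTree.from_paths(2, [(), (2,)]),
        ]
        gaps = [estep_exact(m, t) for t in trees]
        theta = mstep(gaps, trees, gamma=50.0)
        off = ~np.eye(2, dtype=bool)
        assert np.all(np.abs(theta[off]) < 1e-2)


@pytest.fixture(scope="module")
def toy_cohort():
    return [
        MutationTree.from_paths(2, [(), (1,)]),
        MutationTree.from_paths(2, [()]),
        MutationTree.from_paths(2, [(), (1,), (1, 2), (2,)]),
    ]


class TestFit:
    def test_em_matches_mle_on_toy_cohort(self, toy_cohort):
        cfg = FitConfig(gamma=0.5, max_em_iters=500, em_tol=1e-9, seed=0)
        em = fit_em(toy_cohort, cfg)
        mle = fit_mle(toy_cohort, cfg)
        assert np.max(np.abs(em.theta - mle.theta)) < 0.05

    def test_em_objective_monotone_with_exact_estep(self, toy_cohort):
        em = fit_em(toy_cohort, FitConfig(gamma=0.5, max_em_iters=300, em_tol=1e-9, seed=0))
        trace = np.array(em.objective_trace)
        assert len(trace) > 2
        assert np.all(np.diff(trace) >= -1e-10)

    def test_dispatch_by_subtree_threshold(self, toy_cohort):
        assert fit(toy_cohort, FitConfig(gamma=0.5, seed=0)).method == "mle"
        em = fit(toy_cohort, FitConfig(gamma=0.5, subtree_threshold=2, seed=0))
        assert em.method == "em"

    def test_no_mutations_drives_baseline_to_bound(self):
        trees = [MutationTree.from_paths(1, [()]) for _ in range(5)]
        res = fit_mle(trees, FitConfig(gamma=0.5))
        assert res.theta[0, 0] == pytest.approx(-10.0, abs=1e-6)

    def test_large_gamma_gives_diagonal_model(self):
        rng = np.random.default_rng(0)
        truth = random_theta(ThetaPrior(n=3), rng)
        trees = sample_cohort(truth, 50, rng)
        res = fit(trees, FitConfig(gamma=50.0, seed=0))
        off = ~np.eye(3, dtype=bool)
        assert np.all(res.theta[off] == 0.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty cohort"):
            fit([], FitConfig(gamma=0.5))

    def test_mismatched_n_rejected(self):
        trees = [MutationTree.from_paths(2, [()]), MutationTree.from_paths(3, [()])]
        with pytest.raises(ValueError, match="n="):
            fit(trees, FitConfig(gamma=0.5))

    def test_deterministic_given_seed(self, toy_cohort):
        a = fit(toy_cohort, FitConfig(gamma=0.5, seed=3))
        b = fit(toy_cohort, FitConfig(gamma=0.5, seed=3))
        assert np.array_equal(a.theta, b.theta)


def test_sign_recovery_on_simulated_cohorts():
    """Strong off-diagonal effects (|theta| >= 1) are recovered with the right sign."""
    hits, total = 0, 0
    for seed in range(4):
        rng = np.random.default_rng(seed)
        truth = random_theta(ThetaPrior(n=4), rng)
        trees = sample_cohort(truth, 400, rng)
        res = fit(trees, FitConfig(gamma=0.05, seed=seed))
        off = ~np.eye(4, dtype=bool)
        strong = off & (np.abs(truth.theta) >= 1.0)
        if strong.sum() == 0:
            continue
        hits += int(np.sum(np.sign(res.theta[strong]) == np.sign(truth.theta[strong])))
        total += int(strong.sum())
    assert total > 0
    assert hits / total >= 0.7


def test_diagonal_mse_shrinks_with_cohort_size():
    """Mean squared error of the baseline rates decreases from N=50 to N=400."""
    errs = {50: [], 400: []}
    for seed in range(3):
        rng = np.random.default_rng(100 + seed)
        truth = random_theta(ThetaPrior(n=4), rng)
        trees = sample_cohort(truth, 400, rng)
        for n_trees in (50, 400):
            res = fit(trees[:n_trees], FitConfig(gamma=0.05, seed=seed))
            errs[n_trees].append(
                float(np.mean((res.theta.diagonal() - truth.theta.diagonal()) ** 2))
            )
    assert np.mean(errs[400]) < np.mean(errs[50])
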