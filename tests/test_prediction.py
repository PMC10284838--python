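"""Next-event prediction, percentile ranks, retrospective and forward protocols."""

import itertools

import numpy as np
import pytest

from treemhn import (
    MHN,
    MutationTree,
    baseline_models,
    forward_prediction,
    next_event_probabilities,
    percentile_ranks,
    retrospective_pairs,
)

from conftest import random_mhn, random_small_tree


class TestNextEventProbabilities:
    def test_uniform_for_empty_tree_equal_baselines(self):
        m = MHN(theta=np.zeros((3, 3)))
        t = MutationTree.from_paths(3, [()])
        table = next_event_probabilities(m, t)
        assert np.allclose(table.probabilities, 1 / 3)

    def test_promoting_ancestor_shifts_mass(self):
        # mutation 1 promotes mutation 2 fourfold: the in-lineage placement wins
        theta = np.array([[0.0, 0.0], [np.log(4.0), 0.0]])
        m = MHN(theta=theta)
        t = MutationTree.from_paths(2, [(), (1,)])
        table = next_event_probabilities(m, t)
        assert table.probability_of((2,)) == pytest.approx(0.2)
        assert table.probability_of((1, 2)) == pytest.approx(0.8)

    def test_normalized_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(2, 5))
            m = random_mhn(n, rng)
            t = random_small_tree(n, rng)
            from treemhn import augment

            if any(labels for labels in augment(t).next_events.values()):
                table = next_event_probabilities(m, t)
                assert table.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_saturated_tree_rejected(self):
        m = MHN(theta=np.zeros((1, 1)))
        t = MutationTree.from_paths(1, [(), (1,)])
        with pytest.raises(ValueError, match="saturated"):
            next_event_probabilities(m, t)


class TestPercentileRanks:
    def test_ordering(self):
        r = percentile_ranks(np.array([0.8, 0.2]))
        assert r[0] > r[1]

    def test_full_tie_is_fifty(self):
        assert np.allclose(percentile_ranks(np.full(7, 1 / 7)), 50.0)

    def test_distinct_values_follow_midrank_formula(self):
        r = percentile_ranks(np.array([0.1, 0.2, 0.3, 0.4]))
        assert np.allclose(sorted(r), [12.5, 37.5, 62.5, 87.5])

    def test_permutation_and_scale_invariant(self):
        rng = np.random.default_rng(0)
        v = rng.random(9)
        perm = rng.permutation(9)
        assert np.allclose(percentile_ranks(v)[perm], percentile_ranks(v[perm]))
        assert np.allclose(percentile_ranks(v), percentile_ranks(10.0 * v))


class TestRetrospectivePairs:
    def test_chain(self):
        t = MutationTree.from_paths(2, [(), (1,), (1, 2)])
        pairs = retrospective_pairs(t)
        assert [(s.size, v) for s, v in pairs] == [(0, (1,)), (1, (1, 2))]

    def test_two_leaves(self):
        t = MutationTree.from_paths(2, [(), (1,), (2,)])
        assert len(retrospective_pairs(t)) == 4

    def test_count_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            t = random_small_tree(int(rng.integers(2, 5)), rng)
            pairs = retrospective_pairs(t)
            # brute force: every prefix-closed subset of nodes, every boundary node
            nodes = [p for p in t.nodes if p]
            count = 0
            for r in range(len(nodes) + 1):
                for sub in itertools.combinations(nodes, r):
                    s = set(sub) | {()}
                    if any(p[:-1] not in s for p in sub):
                        continue
                    count += sum(1 for p in nodes if p not in s and p[:-1] in s)
            assert len(pairs) == count


class TestForwardPrediction:
    def test_tie_between_two_candidates_ranks_fifty(self):
        m = MHN(theta=np.zeros((2, 2)))
        earlier = MutationTree.from_paths(2, [()])
        later = MutationTree.from_paths(2, [(), (1,)])
        (pred,) = forward_prediction(m, earlier, later)
        assert pred.scoreable
        assert pred.percentile_rank == pytest.approx(50.0)

    def test_promoted_event_gets_top_rank(self):
        theta = np.array([[0.0, 0.0], [np.log(4.0), 0.0]])
        m = MHN(theta=theta)
        earlier = MutationTree.from_paths(2, [(), (1,)])
        later = MutationTree.from_paths(2, [(), (1,), (1, 2)])
        (pred,) = forward_prediction(m, earlier, later)
        assert pred.probability == pytest.approx(0.8)
        assert pred.percentile_rank == pytest.approx(75.0)  # top of 2 candidates

    def test_unscoreable_event_reported_not_dropped(self):
        m = MHN(theta=np.zeros((3, 3)))
        earlier = MutationTree.from_paths(3, [()])
        later = MutationTree.from_paths(3, [(), (1,), (1, 2)])
        preds = {p.event: p for p in forward_prediction(m, earlier, later)}
        assert preds[(1,)].scoreable
        assert not preds[(1, 2)].scoreable  # parent path absent from earlier tree

    def test_no_new_events_returns_empty(self):
        m = MHN(theta=np.zeros((2, 2)))
        t = MutationTree.from_paths(2, [(), (1,)])
        assert forward_prediction(m, t, t) == []


@pytest.fixture(scope="module")
def cohort():
    rng = np.random.default_rng(2)
    from treemhn import ThetaPrior, random_theta, sample_cohort

    truth = random_theta(ThetaPrior(n=3), rng)
    return sample_cohort(truth, 60, rng)


class TestBaselines:
    def test_diagonal_model_has_no_interactions(self, cohort):
        diag_fit, _ = baseline_models(cohort, gamma=0.5)
        off = ~np.eye(3, dtype=bool)
        assert np.all(diag_fit.theta[off] == 0.0)

    def test_diagonal_model_ignores_ancestry(self, cohort):
        diag_fit, _ = baseline_models(cohort, gamma=0.5)
        m = MHN(theta=diag_fit.theta)
        t = MutationTree.from_paths(3, [(), (1,), (2,)])
        table = next_event_probabilities(m, t)
        # mutation 3 is addable at three nodes; same rate everywhere
        p3 = [table.probability_of(e) for e in [(3,), (1, 3), (2, 3)]]
        assert np.allclose(p3, p3[0])

    def test_frequency_model_uniform_frequencies_is_uniform(self):
        from treemhn.prediction import FrequencyModel

        fm = FrequencyModel(n=3, relative_frequency=np.full(3, 1 / 3))
        t = MutationTree.from_paths(3, [(), (1,)])
        table = fm.next_event_probabilities(t)
        assert np.allclose(table.probabilities, 1 / len(table.events))

    def test_both_baselines_normalize(self, cohort):
        diag_fit, freq = baseline_models(cohort, gamma=0.5)
        m = MHN(theta=diag_fit.theta)
        t = MutationTree.from_paths(3, [(), (2,)])
        assert next_event_probabilities(m, t).probabilities.sum() == pytest.approx(1.0)
        assert freq.next_event_probabilities(t).probabilities.sum() == pytest.approx(1.0)
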