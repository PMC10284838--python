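import numpy as np
import pytest

from treemhn import MHN, MutationTree

LOG_HALF = np.log(0.5)


@pytest.fixture
def diag_half_n2() -> MHN:
    """Two mutations, baseline hazards 0.5, no interactions."""
    return MHN(theta=np.array([[LOG_HALF, 0.0], [0.0, LOG_HALF]]))


@pytest.fixture
def chain_tree() -> MutationTree:
    """Chain root -> 1 -> 2 on two mutations."""
    return MutationTree.from_paths(2, [(), (1,), (1, 2)])


@pytest.fixture
def star_tree() -> MutationTree:
    """Root with leaf children 1 and 2."""
    return MutationTree.from_paths(2, [(), (1,), (2,)])


def random_mhn(n: int, rng: np.random.Generator, scale: float = 0.8) -> MHN:
    """Small random network with mildly negative baselines (well-scaled rates)."""
    theta = rng.normal(scale=scale, size=(n, n))
    theta[np.diag_indices(n)] = rng.uniform(-2.0, 0.0, size=n)
    return MHN(theta=theta)


def random_small_tree(n: int, rng: np.random.Generator) -> MutationTree:
    """A random valid tree grown by a few single-event additions."""
    paths = {()}
    for _ in range(int(rng.integers(0, 2 * n))):
        p = sorted(paths)[int(rng.integers(len(paths)))]
        children = {q[-1] for q in paths if q[:-1] == p and len(q) == len(p) + 1}
        choices = [i for i in range(1, n + 1) if i not in p and i not in children]
        if choices:
            paths.add(p + (int(rng.choice(choices)),))
    return MutationTree.from_paths(n, paths)
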