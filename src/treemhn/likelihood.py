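"""Exact marginal tree probability under a hazard network, and its gradient.

The generative process runs independent exponential clocks for every event of
the augmented tree ``A(T)`` and censors at an independent exponential sampling
time.  Marginalizing the sampling time turns the observation probability of a
tree ``T`` into an absorption probability of a continuous-time Markov chain
on the lattice of rooted subtrees of ``T``: from a subtree ``S`` the chain
jumps to ``S + {v}`` with rate ``lambda_v`` for each observed event ``v``
attachable to ``S``, while every attachable unobserved event of
``A(T) \\ T`` adds to the exit rate and leads out of the lattice.  With
states ordered subsets-before-supersets the resolvent ``lambda_s*I - Q`` is
triangular, so

    p(T | Theta) = lambda_s * [(lambda_s*I - Q)^{-1}]_{root, T}

is obtained by a single forward substitution, and all partial derivatives
with respect to the event rates by one reverse (adjoint) sweep.
"""

from __future__ import annotations

import numpy as np

from .model import (
    DEFAULT_LATTICE_CAP,
    LOG_RATE_CAP,
    MHN,
    MutationTree,
    Path,
    augment,
    enumerate_subtree_lattice,
)

__all__ = [
    "TreeLikelihoodWorkspace",
    "tree_probability",
    "tree_log_likelihood",
    "tree_log_likelihood_grad",
    "mc_tree_probability",
]


_WORKSPACE_CACHE: dict = {}
_WORKSPACE_CACHE_MAX = 4096


def workspace_for(tree: MutationTree, cap: int = DEFAULT_LATTICE_CAP) -> "TreeLikelihoodWorkspace":
    """Shared, cached workspace for a tree (keyed by canonical form).

    Workspaces are immutable after construction (evaluation methods take
    ``theta`` as an argument), so one instance can serve every fit that sees
    the same tree — subsampled refits in particular.
    """
    key = (tree.paths, tree.n, cap)
    ws = _WORKSPACE_CACHE.get(key)
    if ws is None:
        if len(_WORKSPACE_CACHE) >= _WORKSPACE_CACHE_MAX:
            _WORKSPACE_CACHE.clear()
        ws = TreeLikelihoodWorkspace(tree, cap=cap)
        _WORKSPACE_CACHE[key] = ws
    return ws


class TreeLikelihoodWorkspace:
    """Precomputed structure of one tree, reused across likelihood evaluations.

    Event tables (every event of ``A(T)``, with its parent path, label and
    ancestor-indicator row) are always built; the subtree lattice and the
    state/transition tables needed for the exact likelihood are built lazily,
    so that trees above the subtree cap can still use the event tables for
    Monte-Carlo E-steps.
    """

    def __init__(self, tree: MutationTree, cap: int = DEFAULT_LATTICE_CAP):
        self.tree = tree
        self.cap = cap
        n = tree.n
        aug = augment(tree)
        events: list[tuple[Path, int, bool]] = list(aug.events())
        self.events = events
        self.n_events = len(events)
        self.ev_parent = [e[0] for e in events]
        self.ev_label = np.array([e[1] - 1 for e in events], dtype=np.intp)
        self.ev_observed = np.array([e[2] for e in events], dtype=bool)
        # Ancestor indicator: anc[e, j] = 1 iff mutation j+1 lies on the parent path.
        anc = np.zeros((self.n_events, n), dtype=float)
        for e, (p, _, _) in enumerate(events):
            for j in p:
                anc[e, j - 1] = 1.0
        self.anc = anc
        self._event_index = {(p, i): e for e, (p, i, _) in enumerate(events)}
        self._lattice_built = False

    # -- rates --------------------------------------------------------------

    def log_rates(self, theta: np.ndarray) -> np.ndarray:
        """Log-hazard of every event of ``A(T)`` under ``theta``."""
        lab = self.ev_label
        log_lam = theta[lab, lab] + np.einsum("ej,ej->e", self.anc, theta[lab, :])
        return np.minimum(log_lam, LOG_RATE_CAP)

    def rates(self, theta: np.ndarray) -> np.ndarray:
        return np.exp(self.log_rates(theta))

    def event_index(self, path: Path, label: int) -> int:
        return self._event_index[(tuple(path), label)]

    # -- lattice ------------------------------------------------------------

    def _build_lattice(self) -> None:
        if self._lattice_built:
            return
        lattice = enumerate_subtree_lattice(self.tree, cap=self.cap)
        self.lattice = lattice
        index = lattice.index
        att_state: list[int] = []
        att_event: list[int] = []
        tr_from: list[int] = []
        tr_to: list[int] = []
        tr_event: list[int] = []
        tree_paths = self.tree.paths
        for s_idx, state in enumerate(lattice.states):
            for e, (p, i, observed) in enumerate(self.events):
                if p not in state:
                    continue
                child = p + (i,)
                if child in state:
                    continue
                att_state.append(s_idx)
                att_event.append(e)
                if observed and child in tree_paths:
                    target = index[state | {child}]
                    tr_from.append(s_idx)
                    tr_to.append(target)
                    tr_event.append(e)
        self.att_state = np.array(att_state, dtype=np.intp)
        self.att_event = np.array(att_event, dtype=np.intp)
        order = np.argsort(np.array(tr_to, dtype=np.intp), kind="stable")
        self.tr_from = np.array(tr_from, dtype=np.intp)[order]
        self.tr_to = np.array(tr_to, dtype=np.intp)[order]
        self.tr_event = np.array(tr_event, dtype=np.intp)[order]
        # Incoming-transition slices per state, in state order.
        n_states = len(lattice.states)
        starts = np.searchsorted(self.tr_to, np.arange(n_states + 1))
        self._in_slices = starts
        self._lattice_built = True

    @property
    def n_states(self) -> int:
        self._build_lattice()
        return len(self.lattice.states)

    # -- forward / adjoint passes -------------------------------------------

    def _forward(self, lam: np.ndarray, lambda_s: float):
        self._build_lattice()
        n_states = len(self.lattice.states)
        den = np.full(n_states, lambda_s)
        np.add.at(den, self.att_state, lam[self.att_event])
        x = np.zeros(n_states)
        x[0] = 1.0 / den[0]
        starts = self._in_slices
        tf, tt, te = self.tr_from, self.tr_to, self.tr_event
        for s in range(1, n_states):
            lo, hi = starts[s], starts[s + 1]
            x[s] = float(np.dot(x[tf[lo:hi]], lam[te[lo:hi]])) / den[s]
        return x, den

    def probability(self, theta: np.ndarray, lambda_s: float) -> float:
        lam = self.rates(theta)
        x, _ = self._forward(lam, lambda_s)
        p = lambda_s * x[-1]
        if not (np.isfinite(p) and p > 0):
            raise FloatingPointError(
                f"non-finite tree probability for tree {self.tree.tree_id!r}"
            )
        return float(p)

    def dlogp_dlam(self, theta: np.ndarray, lambda_s: float):
        """Per-event-rate partials of the log tree probability.

        Returns ``(log_p, lam, g)`` with ``g[e] = d log p / d lambda_e`` for
        every event ``e`` of ``A(T)``.
        """
        lam = self.rates(theta)
        x, den = self._forward(lam, lambda_s)
        n_states = x.shape[0]
        if not (np.isfinite(x[-1]) and x[-1] > 0):
            raise FloatingPointError(
                f"non-finite forward solve for tree {self.tree.tree_id!r}"
            )
        # Adjoint a[s] = d x_last / d x_s, accumulated backwards.
        a = np.zeros(n_states)
        a[-1] = 1.0
        starts = self._in_slices
        tf, tt, te = self.tr_from, self.tr_to, self.tr_event
        for s in range(n_states - 1, 0, -1):
            lo, hi = starts[s], starts[s + 1]
            if lo == hi:
                continue
            np.add.at(a, tf[lo:hi], a[s] * lam[te[lo:hi]] / den[s])
        g = np.zeros(self.n_events)
        # Numerator occurrences: transition s' -> s carries lambda_e.
        np.add.at(g, te, a[tt] * x[tf] / den[tt])
        # Denominator occurrences: every attachable event inflates den[s].
        np.add.at(g, self.att_event, -a[self.att_state] * x[self.att_state] / den[self.att_state])
        g /= x[-1]
        log_p = np.log(lambda_s) + np.log(x[-1])
        return float(log_p), lam, g

    def log_likelihood_and_grad(self, theta: np.ndarray, lambda_s: float):
        """Log probability and its gradient with respect to ``theta``.

        Chain rule through the event rates: ``d log p / d theta_kk`` sums
        ``lambda_v * d log p / d lambda_v`` over events with label ``k``;
        the off-diagonal ``theta_kj`` additionally requires ``j`` on the
        event's parent path.
        """
        log_p, lam, g = self.dlogp_dlam(theta, lambda_s)
        c = lam * g
        grad = np.zeros_like(theta)
        lab = self.ev_label
        np.add.at(grad, lab, c[:, None] * self.anc)
        np.add.at(grad, (lab, lab), c)
        return log_p, grad


def tree_probability(
    mhn: MHN, tree: MutationTree, cap: int = DEFAULT_LATTICE_CAP
) -> float:
    """Exact marginal probability ``p(T | Theta)`` of observing ``tree``."""
    ws = TreeLikelihoodWorkspace(tree, cap=cap)
    return ws.probability(mhn.theta, mhn.sampling_rate)


def tree_log_likelihood(
    mhn: MHN, tree: MutationTree, cap: int = DEFAULT_LATTICE_CAP
) -> float:
    ws = TreeLikelihoodWorkspace(tree, cap=cap)
    return float(np.log(ws.probability(mhn.theta, mhn.sampling_rate)))


def tree_log_likelihood_grad(
    mhn: MHN, tree: MutationTree, cap: int = DEFAULT_LATTICE_CAP
) -> np.ndarray:
    """Gradient ``d log p(T | Theta) / d theta`` as an ``n x n`` matrix."""
    ws = TreeLikelihoodWorkspace(tree, cap=cap)
    _, grad = ws.log_likelihood_and_grad(mhn.theta, mhn.sampling_rate)
    return grad


def mc_tree_probability(
    mhn: MHN,
    tree: MutationTree,
    samples: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Brute-force generative estimate of ``p(T | Theta)``.

    Simulates the full tree-generating process ``samples`` times and returns
    the fraction of runs whose observed tree equals ``tree`` (canonical
    path-set equality), with the binomial standard error.
    """
    from .simulate import sample_tree

    if samples < 1:
        raise ValueError("samples must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    target = tree.paths
    hits = 0
    for _ in range(samples):
        t = sample_tree(mhn, rng)
        if t.paths == target:
            hits += 1
    p_hat = hits / samples
    se = float(np.sqrt(max(p_hat * (1.0 - p_hat), 1.0 / samples) / samples))
    return p_hat, se
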