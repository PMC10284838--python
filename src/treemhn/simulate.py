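"""Synthetic-data backbone: ground-truth networks, the tree-generating
process, tree perturbation, and benchmark metrics.

The generator mirrors the study conditions under which the model is usually
assessed: baseline log-rates uniform on [-6, -1] (mutations rarer than the
sampling clock), half of the off-diagonal interactions zero, the remainder
gamma-distributed in magnitude with a random sign.  Cohorts drawn this way
are dominated by small trees, as in real single-cell panel data.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import MHN, MutationTree, Path, count_subtrees

__all__ = [
    "ThetaPrior",
    "NoiseConfig",
    "random_theta",
    "sample_tree",
    "sample_cohort",
    "perturb_tree",
    "perturb_cohort",
    "edge_recovery_metrics",
    "BenchmarkConfig",
    "benchmark_run",
]

logger = logging.getLogger(__name__)

MAX_TREE_NODES = 100_000


@dataclass(frozen=True)
class ThetaPrior:
    """Distribution over ground-truth hazard networks.

    Diagonals (baseline log-rates) are uniform on ``[diag_low, diag_high]``.
    Each off-diagonal is zero with probability ``sparsity``; otherwise its
    magnitude is Gamma(``gamma_shape``, rate ``gamma_rate``) — mean 1.6 at the
    defaults — and its sign is negative with probability
    ``negative_fraction``.  ``gamma_param`` selects whether ``gamma_rate`` is
    read as a rate (default) or a scale.
    """

    n: int
    diag_low: float = -6.0
    diag_high: float = -1.0
    sparsity: float = 0.5
    gamma_shape: float = 4.0
    gamma_rate: float = 2.5
    negative_fraction: float = 0.5
    gamma_param: str = "rate"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if not (0.0 <= self.sparsity <= 1.0 and 0.0 <= self.negative_fraction <= 1.0):
            raise ValueError("sparsity and negative_fraction must lie in [0, 1]")
        if self.gamma_shape <= 0 or self.gamma_rate <= 0:
            raise ValueError("gamma parameters must be positive")
        if self.gamma_param not in ("rate", "scale"):
            raise ValueError("gamma_param must be 'rate' or 'scale'")


@dataclass(frozen=True)
class NoiseConfig:
    """Per-node tree perturbation: probability ``epsilon`` and kind."""

    epsilon: float
    kind: str = "mixed"

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in [0, 1]")
        if self.kind not in ("relabel", "prune_reattach", "mixed"):
            raise ValueError("kind must be relabel | prune_reattach | mixed")


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_theta(
    prior: ThetaPrior, seed: int | np.random.Generator | None = None
) -> MHN:
    """Draw a ground-truth hazard network from ``prior``."""
    rng = _rng(seed)
    n = prior.n
    theta = np.zeros((n, n))
    diag = rng.uniform(prior.diag_low, prior.diag_high, size=n)
    scale = 1.0 / prior.gamma_rate if prior.gamma_param == "rate" else prior.gamma_rate
    off = rng.gamma(prior.gamma_shape, scale, size=(n, n))
    signs = np.where(rng.random((n, n)) < prior.negative_fraction, -1.0, 1.0)
    zeros = rng.random((n, n)) < prior.sparsity
    theta = off * signs
    theta[zeros] = 0.0
    theta[np.diag_indices(n)] = diag
    return MHN(theta=theta)


def sample_tree(
    mhn: MHN,
    seed: int | np.random.Generator | None = None,
    tree_id: str = "",
    patient_id: str = "",
) -> MutationTree:
    """Draw one mutation tree from the generative process.

    An independent exponential sampling time ``T_s ~ Exp(lambda_s)`` is
    drawn; starting from the root at time 0, every addable mutation ``i`` of
    a live subclone ``pi`` gets an exponential waiting gap with rate
    ``lambda_(pi, i)``, and the child subclone is kept (and itself expanded)
    iff its absolute time falls before ``T_s``.
    """
    rng = _rng(seed)
    n = mhn.n
    theta = mhn.theta
    t_s = rng.exponential(1.0 / mhn.sampling_rate)
    paths: set[Path] = {()}
    queue: deque[tuple[Path, float]] = deque([((), 0.0)])
    while queue:
        p, t_p = queue.popleft()
        on_path = set(p)
        for i in range(1, n + 1):
            if i in on_path:
                continue
            k = i - 1
            log_lam = theta[k, k] + sum(theta[k, j - 1] for j in p)
            gap = rng.exponential(np.exp(-min(log_lam, 30.0)))
            t_child = t_p + gap
            if t_child < t_s:
                child = p + (i,)
                paths.add(child)
                queue.append((child, t_child))
                if len(paths) > MAX_TREE_NODES:
                    raise RuntimeError(
                        f"runaway tree growth (> {MAX_TREE_NODES} nodes) under "
                        f"theta with max diagonal {theta.diagonal().max():.2f}"
                    )
    return MutationTree(n=n, paths=frozenset(paths), tree_id=tree_id, patient_id=patient_id)


def sample_cohort(
    mhn: MHN,
    n_trees: int,
    seed: int | np.random.Generator | None = None,
    patient_prefix: str = "P",
) -> list[MutationTree]:
    """Draw an i.i.d. cohort of ``n_trees`` mutation trees."""
    rng = _rng(seed)
    return [
        sample_tree(mhn, rng, tree_id=f"T{k + 1}", patient_id=f"{patient_prefix}{k + 1}")
        for k in range(n_trees)
    ]


# ---------------------------------------------------------------------------
# Tree perturbation (noise model)
# ---------------------------------------------------------------------------


def _rebase(paths: set[Path], old: Path, new: Path) -> set[Path]:
    d = len(old)
    out = set()
    for p in paths:
        if p[:d] == old:
            out.add(new + p[d:])
        else:
            out.add(p)
    return out


def _relabel(paths: set[Path], node: Path, n: int, rng: np.random.Generator) -> set[Path] | None:
    parent = node[:-1]
    sibling_labels = {p[-1] for p in paths if p[:-1] == parent and len(p) == len(node)}
    below = {lab for p in paths if p[: len(node)] == node for lab in p[len(node):]}
    forbidden = set(parent) | sibling_labels | below | {node[-1]}
    choices = [i for i in range(1, n + 1) if i not in forbidden]
    if not choices:
        return None
    new_label = int(rng.choice(choices))
    return _rebase(paths, node, parent + (new_label,))


def _prune_reattach(
    paths: set[Path], node: Path, n: int, rng: np.random.Generator
) -> set[Path] | None:
    subtree = {p for p in paths if p[: len(node)] == node}
    sub_labels = {lab for p in subtree for lab in p[len(node) - 1:]}
    candidates = []
    for host in sorted(paths - subtree, key=lambda p: (len(p), p)):
        if set(host) & sub_labels:
            continue
        host_children = {p[-1] for p in paths - subtree if p[:-1] == host and len(p) == len(host) + 1}
        if node[-1] in host_children:
            continue
        candidates.append(host)
    if not candidates:
        return None
    host = candidates[int(rng.integers(len(candidates)))]
    kept = paths - subtree
    moved = {host + (node[-1],) + p[len(node):] for p in subtree}
    return kept | moved


def perturb_tree(
    tree: MutationTree,
    noise: NoiseConfig,
    seed: int | np.random.Generator | None = None,
) -> MutationTree:
    """Independently perturb each non-root node with probability ``epsilon``.

    ``relabel`` replaces the node's mutation by a uniformly chosen label that
    keeps lineage and sibling distinctness; ``prune_reattach`` detaches the
    node's subtree and reattaches it below a uniformly chosen valid host;
    ``mixed`` flips a fair coin between the two.  Nodes for which no valid
    move exists are skipped.  The output is always a valid tree, and
    ``epsilon = 0`` is the identity.
    """
    rng = _rng(seed)
    if noise.epsilon == 0.0:
        return tree
    paths = set(tree.paths)
    for node in sorted(tree.paths, key=lambda p: (len(p), p)):
        if not node or node not in paths:
            continue
        if rng.random() >= noise.epsilon:
            continue
        kind = noise.kind
        if kind == "mixed":
            kind = "relabel" if rng.random() < 0.5 else "prune_reattach"
        move = _relabel if kind == "relabel" else _prune_reattach
        new_paths = move(paths, node, tree.n, rng)
        if new_paths is None:
            logger.debug("no valid %s move for node %s in tree %s", kind, node, tree.tree_id)
            continue
        paths = new_paths
    return MutationTree(
        n=tree.n,
        paths=frozenset(paths),
        tree_id=tree.tree_id,
        patient_id=tree.patient_id,
        weight=tree.weight,
    )


def perturb_cohort(
    trees: Sequence[MutationTree],
    noise: NoiseConfig,
    seed: int | np.random.Generator | None = None,
) -> list[MutationTree]:
    rng = _rng(seed)
    return [perturb_tree(t, noise, rng) for t in trees]


# ---------------------------------------------------------------------------
# Benchmark metrics
# ---------------------------------------------------------------------------


def edge_recovery_metrics(
    theta_true: np.ndarray,
    theta_hat: np.ndarray,
    top_fraction: float = 1.0,
) -> tuple[float | None, float | None]:
    """Sign-aware precision and recall of the off-diagonal support.

    An estimated off-diagonal entry is a true positive iff it is non-zero and
    has the same sign as the true entry.  With ``top_fraction < 1`` the
    comparison is restricted to the mutations with the highest true baseline
    rates (rows and columns among the top ``ceil(top_fraction * n)``).
    Empty denominators yield ``None``.
    """
    theta_true = np.asarray(theta_true, dtype=float)
    theta_hat = np.asarray(theta_hat, dtype=float)
    if theta_true.shape != theta_hat.shape:
        raise ValueError("theta_true and theta_hat must share a shape")
    n = theta_true.shape[0]
    k = int(np.ceil(top_fraction * n))
    top = np.argsort(-theta_true.diagonal(), kind="stable")[:k]
    mask = np.zeros((n, n), dtype=bool)
    mask[np.ix_(top, top)] = True
    mask[np.diag_indices(n)] = False
    true_nz = (theta_true != 0) & mask
    est_nz = (theta_hat != 0) & mask
    tp = int(np.sum(est_nz & true_nz & (np.sign(theta_hat) == np.sign(theta_true))))
    n_est = int(np.sum(est_nz))
    n_true = int(np.sum(true_nz))
    precision = tp / n_est if n_est else None
    recall = tp / n_true if n_true else None
    return precision, recall


@dataclass(frozen=True)
class BenchmarkConfig:
    """Scaled-down simulation study: per repetition, draw a truth network,
    simulate a cohort, optionally perturb it, fit, and score recovery."""

    n_mutations: Sequence[int] = (8,)
    n_trees: Sequence[int] = (200,)
    gammas: Sequence[float] = (0.5,)
    repetitions: int = 5
    epsilon: float = 0.0
    noise_kind: str = "mixed"
    kl_length: int = 4
    top_fraction: float = 0.5
    stability: bool = False
    seed: int = 0
    prior_overrides: dict = field(default_factory=dict)


def benchmark_run(config: BenchmarkConfig) -> pd.DataFrame:
    """Run the simulation benchmark and return one row per repetition x gamma.

    Columns: configuration, sign-aware precision/recall (top mutations by
    baseline rate), and the KL divergences between the true and fitted
    fixed-length trajectory distributions (headline direction: from the
    estimate to the truth, ``KL(P_truth || P_estimate)``).
    """
    from .estimation import FitConfig, fit
    from .trajectories import fixed_length_distribution, kl_divergence

    rows = []
    ss = np.random.SeedSequence(config.seed)
    for n in config.n_mutations:
        for n_trees in config.n_trees:
            for rep in range(config.repetitions):
                child = ss.spawn(1)[0]
                rng = np.random.default_rng(child)
                prior = ThetaPrior(n=n, **config.prior_overrides)
                truth = random_theta(prior, rng)
                trees = sample_cohort(truth, n_trees, rng)
                if config.epsilon > 0:
                    trees = perturb_cohort(
                        trees, NoiseConfig(config.epsilon, config.noise_kind), rng
                    )
                d = min(config.kl_length, n)
                p_true = fixed_length_distribution(truth, d)
                for gamma in config.gammas:
                    try:
                        fit_seed = int(rng.integers(2**31 - 1))
                        result = fit(trees, FitConfig(gamma=gamma, seed=fit_seed))
                        est = MHN(result.theta, sampling_rate=truth.sampling_rate)
                        precision, recall = edge_recovery_metrics(
                            truth.theta, result.theta, config.top_fraction
                        )
                        p_est = fixed_length_distribution(est, d)
                        rows.append(
                            {
                                "n": n,
                                "N": n_trees,
                                "rep": rep,
                                "gamma": gamma,
                                "epsilon": config.epsilon,
                                "precision": precision,
                                "recall": recall,
                                "kl_truth_vs_estimate": kl_divergence(p_true, p_est),
                                "kl_estimate_vs_truth": kl_divergence(p_est, p_true),
                                "converged": result.converged,
                            }
                        )
                    except Exception:  # noqa: BLE001 - keep the sweep alive
                        logger.exception(
                            "benchmark repetition failed (n=%d N=%d rep=%d gamma=%g)",
                            n,
                            n_trees,
                            rep,
                            gamma,
                        )
    return pd.DataFrame(rows)
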