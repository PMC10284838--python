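"""Penalized maximum-likelihood estimation of the hazard network.

Two routes share one objective, the L1-penalized log-likelihood

    sum_l log p(T_l | Theta)  -  gamma * sum_{i != j} |theta_ij| :

* direct quasi-Newton ascent (L-BFGS-B) on the exact likelihood, used when
  every tree's subtree lattice is small enough, and
* an EM algorithm whose E-step computes the expected latent waiting-time gap
  of every event of ``A(T)`` — exactly for small trees, by self-normalized
  importance sampling for large ones — and whose M-step maximizes the
  resulting concave expected complete-data objective.

The L1 term is handled by the smooth surrogate ``|x| ~ sqrt(x^2 + delta)``
with tiny ``delta``; off-diagonals below ``zero_tol`` in magnitude are
reported as exact zeros (support recovery proper is the job of stability
selection, not of a single fit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .model import MHN, MutationTree, Path, count_subtrees
from .likelihood import TreeLikelihoodWorkspace, workspace_for

__all__ = [
    "FitConfig",
    "FitResult",
    "fit",
    "fit_mle",
    "fit_em",
    "estep_exact",
    "estep_mc",
    "mstep",
    "initial_theta",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Settings shared by the MLE and EM fitting routes.

    ``gamma`` is the L1 penalty weight (must be positive); ``subtree_threshold``
    dispatches between exact MLE and MC-EM (default 500 subtrees);
    ``mc_samples`` is the number of importance samples per tree and EM
    iteration (default 300).
    """

    gamma: float = 0.5
    sampling_rate: float = 1.0
    subtree_threshold: int = 500
    mc_samples: int = 300
    max_em_iters: int = 200
    em_tol: float = 1e-6
    max_opt_iters: int = 500
    opt_tol: float = 1e-8
    zero_tol: float = 1e-2
    l1_delta: float = 1e-8
    theta_bound: float = 10.0
    lattice_cap: int = 50_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if self.mc_samples < 1 or self.subtree_threshold < 1:
            raise ValueError("mc_samples and subtree_threshold must be positive")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")


@dataclass(frozen=True)
class FitResult:
    """Estimated network plus fitting diagnostics."""

    theta: np.ndarray
    gamma: float
    method: str  # "mle" | "em"
    converged: bool
    objective_trace: tuple[float, ...]
    n_iterations: int
    tree_methods: tuple[str, ...] = ()  # per distinct tree: "exact" | "mc"

    @property
    def log_likelihood(self) -> float:
        """Final penalized objective value."""
        return self.objective_trace[-1]

    def mhn(self, sampling_rate: float = 1.0) -> MHN:
        return MHN(theta=self.theta, sampling_rate=sampling_rate)


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------


def _check_cohort(trees: Sequence[MutationTree]) -> int:
    if len(trees) == 0:
        raise ValueError("empty cohort: at least one tree is required")
    n = trees[0].n
    for t in trees:
        if t.n != n:
            raise ValueError(
                f"tree {t.tree_id!r} has n={t.n}, cohort expects n={n}"
            )
    return n


def _dedupe(trees: Sequence[MutationTree]) -> tuple[list[MutationTree], np.ndarray]:
    """Group identical trees; likelihood terms are weighted by multiplicity.

    Per-tree weights multiply into the grouping, so posterior-weighted
    cohorts are supported transparently.
    """
    groups: dict[frozenset[Path], tuple[MutationTree, float]] = {}
    for t in trees:
        key = t.paths
        if key in groups:
            rep, w = groups[key]
            groups[key] = (rep, w + t.weight)
        else:
            groups[key] = (t, t.weight)
    reps = [rep for rep, _ in groups.values()]
    weights = np.array([w for _, w in groups.values()], dtype=float)
    return reps, weights


def _penalty(theta: np.ndarray, gamma: float, delta: float) -> tuple[float, np.ndarray]:
    off = ~np.eye(theta.shape[0], dtype=bool)
    s = np.sqrt(theta**2 + delta)
    value = gamma * float(np.sum(s[off]))
    grad = np.zeros_like(theta)
    grad[off] = gamma * theta[off] / s[off]
    return value, grad


def initial_theta(trees: Sequence[MutationTree], n: int) -> np.ndarray:
    """Frequency-based starting point: independent-rate guess, zero off-diagonals.

    ``theta_ii = log(m_i / N) - log(mean tree size + 1)`` with ``m_i`` the
    number of trees containing mutation ``i``, clipped to ``[-8, 2]``.
    """
    n_trees = len(trees)
    m = np.zeros(n)
    for t in trees:
        for i in t.mutations():
            m[i - 1] += 1
    m = np.maximum(m, 0.5)
    mean_size = float(np.mean([t.size for t in trees]))
    diag = np.clip(np.log(m / n_trees) - np.log(mean_size + 1.0), -8.0, 2.0)
    theta0 = np.zeros((n, n))
    theta0[np.diag_indices(n)] = diag
    return theta0


def _bounds(n: int, bound: float, support: np.ndarray | None) -> list[tuple[float, float]]:
    """Box bounds per entry; off-diagonals outside ``support`` are pinned at 0."""
    out = []
    for i in range(n):
        for j in range(n):
            if i != j and support is not None and not support[i, j]:
                out.append((0.0, 0.0))
            else:
                out.append((-bound, bound))
    return out


def _threshold(theta: np.ndarray, zero_tol: float) -> np.ndarray:
    out = theta.copy()
    off = ~np.eye(theta.shape[0], dtype=bool)
    out[off & (np.abs(out) < zero_tol)] = 0.0
    return out


# ---------------------------------------------------------------------------
# Direct penalized MLE
# ---------------------------------------------------------------------------


def fit_mle(
    trees: Sequence[MutationTree],
    config: FitConfig,
    support: np.ndarray | None = None,
    theta0: np.ndarray | None = None,
) -> FitResult:
    """Maximize the penalized exact log-likelihood by L-BFGS-B.

    ``support`` (boolean ``n x n``) optionally restricts which off-diagonals
    are free; entries outside it are pinned to zero (used by stability
    selection refits and the diagonal-only baseline).
    """
    n = _check_cohort(trees)
    reps, weights = _dedupe(trees)
    workspaces = [workspace_for(t, cap=config.lattice_cap) for t in reps]
    lam_s = config.sampling_rate
    if theta0 is None:
        theta0 = initial_theta(trees, n)
    if support is not None:
        theta0 = theta0.copy()
        theta0[~np.eye(n, dtype=bool) & ~support] = 0.0

    trace: list[float] = []

    def negobj(x: np.ndarray) -> tuple[float, np.ndarray]:
        theta = x.reshape(n, n)
        total = 0.0
        grad = np.zeros((n, n))
        for ws, w in zip(workspaces, weights):
            lp, g = ws.log_likelihood_and_grad(theta, lam_s)
            total += w * lp
            grad += w * g
        pen, pen_grad = _penalty(theta, config.gamma, config.l1_delta)
        trace.append(total - pen)
        return -(total - pen), (pen_grad - grad).ravel()

    res = minimize(
        negobj,
        theta0.ravel(),
        jac=True,
        method="L-BFGS-B",
        bounds=_bounds(n, config.theta_bound, support),
        options={"maxiter": config.max_opt_iters, "ftol": config.opt_tol, "gtol": 1e-6},
    )
    theta_hat = _threshold(res.x.reshape(n, n), config.zero_tol)
    if not res.success:
        logger.warning("MLE optimizer did not report convergence: %s", res.message)
    return FitResult(
        theta=theta_hat,
        gamma=config.gamma,
        method="mle",
        converged=bool(res.success),
        objective_trace=(trace[0], -float(res.fun)),
        n_iterations=int(res.nit),
        tree_methods=tuple("exact" for _ in reps),
    )


# ---------------------------------------------------------------------------
# E-steps
# ---------------------------------------------------------------------------


def _estep_exact_ws(
    ws: TreeLikelihoodWorkspace, theta: np.ndarray, lam_s: float
) -> np.ndarray:
    _, lam, g = ws.dlogp_dlam(theta, lam_s)
    # E[T_(pi,i) - T_pi | T, Theta] = 1/lambda - d log p / d lambda.
    return 1.0 / lam - g


def estep_exact(mhn: MHN, tree: MutationTree, cap: int = 50_000) -> dict[tuple[Path, int], float]:
    """Exact conditional expected waiting-time gap of every event of ``A(T)``.

    For an observed event the gap is truncated below the sampling time, so
    the expectation is at most the unconditional mean ``1/lambda``; for an
    unobserved next event it exceeds ``1/lambda``.
    """
    ws = workspace_for(tree, cap=cap)
    gaps = _estep_exact_ws(ws, mhn.theta, mhn.sampling_rate)
    return {(p, i): float(z) for (p, i, _), z in zip(ws.events, gaps)}


def _sample_texp(
    rng: np.random.Generator, lam: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Draw exponentials with rates ``lam`` truncated to ``(0, b)`` by inverse CDF."""
    u = rng.random(lam.shape)
    # -log(1 - u * (1 - exp(-lam*b))) / lam, computed stably.
    tail = -np.expm1(-lam * b)  # 1 - exp(-lam b)
    return -np.log1p(-u * tail) / lam


def _estep_mc_ws(
    ws: TreeLikelihoodWorkspace,
    theta: np.ndarray,
    lam_s: float,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Self-normalized importance-sampling estimate of the expected gaps.

    The proposal draws the sampling time, then — following the topological
    order of the tree — truncated-exponential gaps that are compatible with
    the tree by construction: observed events before the sampling time,
    unobserved next events after it.  Weights multiply, per observed event,
    the probability mass below the residual time and, per unobserved event,
    the mass above it.
    """
    lam = ws.rates(theta)
    M = n_samples
    t_s = rng.exponential(1.0 / lam_s, size=M)
    node_time: dict[Path, np.ndarray] = {(): np.zeros(M)}
    Z = np.empty((ws.n_events, M))
    log_w = np.zeros(M)
    # Events sorted by parent depth give a valid topological order.
    order = sorted(range(ws.n_events), key=lambda e: len(ws.ev_parent[e]))
    for e in order:
        p = ws.ev_parent[e]
        t_p = node_time[p]
        residual = t_s - t_p  # > 0 by construction
        if ws.ev_observed[e]:
            z = _sample_texp(rng, np.full(M, lam[e]), residual)
            node_time[p + (ws.ev_label[e] + 1,)] = t_p + z
            log_w += np.log(-np.expm1(-lam[e] * residual))
        else:
            z = residual + rng.exponential(1.0 / lam[e], size=M)
            log_w += -lam[e] * residual
        Z[e] = z
    log_w -= log_w.max()
    w = np.exp(log_w)
    w_sum = float(w.sum())
    if not np.isfinite(w_sum) or w_sum <= 0:
        ess = 0.0
        raise FloatingPointError(
            f"degenerate importance weights (effective sample size {ess:.1f}) "
            f"for tree {ws.tree.tree_id!r}"
        )
    return (Z @ w) / w_sum


def estep_mc(
    mhn: MHN,
    tree: MutationTree,
    n_samples: int,
    seed: int | np.random.Generator | None = None,
) -> dict[tuple[Path, int], float]:
    """Monte-Carlo (importance-sampled) expected waiting-time gaps."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ws = TreeLikelihoodWorkspace(tree)  # no lattice needed
    gaps = _estep_mc_ws(ws, mhn.theta, mhn.sampling_rate, n_samples, rng)
    return {(p, i): float(z) for (p, i, _), z in zip(ws.events, gaps)}


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------


def _mstep_arrays(
    workspaces: Sequence[TreeLikelihoodWorkspace],
    gaps: Sequence[np.ndarray],
    weights: np.ndarray,
    gamma: float,
    config: FitConfig,
    theta0: np.ndarray,
    support: np.ndarray | None = None,
) -> np.ndarray:
    n = theta0.shape[0]

    def negobj(x: np.ndarray) -> tuple[float, np.ndarray]:
        theta = x.reshape(n, n)
        total = 0.0
        grad = np.zeros((n, n))
        for ws, ez, w in zip(workspaces, gaps, weights):
            log_lam = ws.log_rates(theta)
            lam = np.exp(log_lam)
            total += w * float(np.sum(log_lam - lam * ez))
            coef = w * (1.0 - lam * ez)
            lab = ws.ev_label
            np.add.at(grad, lab, coef[:, None] * ws.anc)
            np.add.at(grad, (lab, lab), coef)
        pen, pen_grad = _penalty(theta, gamma, config.l1_delta)
        return -(total - pen), (pen_grad - grad).ravel()

    res = minimize(
        negobj,
        theta0.ravel(),
        jac=True,
        method="L-BFGS-B",
        bounds=_bounds(n, config.theta_bound, support),
        options={"maxiter": config.max_opt_iters, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success:
        logger.warning("M-step optimizer did not report convergence: %s", res.message)
    return res.x.reshape(n, n)


def mstep(
    expected_gaps: Sequence[dict[tuple[Path, int], float]],
    trees: Sequence[MutationTree],
    gamma: float,
    config: FitConfig | None = None,
) -> np.ndarray:
    """Maximize the penalized expected complete-data log-likelihood.

    Every event of ``A(T)`` contributes its log-rate and ``-rate * E[gap]``
    (all latent waiting gaps are realized in the complete-data likelihood);
    the objective is concave in ``theta``.
    """
    config = config or FitConfig(gamma=gamma)
    n = _check_cohort(trees)
    workspaces = [TreeLikelihoodWorkspace(t) for t in trees]  # event tables only
    gaps = []
    for ws, table in zip(workspaces, expected_gaps):
        arr = np.array([table[(p, i)] for (p, i, _) in ws.events], dtype=float)
        if np.any(arr <= 0):
            raise ValueError("expected gaps must be strictly positive")
        gaps.append(arr)
    weights = np.ones(len(trees))
    return _mstep_arrays(
        workspaces, gaps, weights, gamma, config, initial_theta(trees, n)
    )


# ---------------------------------------------------------------------------
# Hybrid EM and the dispatching front door
# ---------------------------------------------------------------------------


def fit_em(
    trees: Sequence[MutationTree],
    config: FitConfig,
    support: np.ndarray | None = None,
    theta0: np.ndarray | None = None,
) -> FitResult:
    """Hybrid EM: exact E-step for small trees, importance-sampled for large.

    A fresh Monte-Carlo seed is derived from the master seed at every EM
    iteration, so the whole fit is reproducible given ``config.seed``.
    """
    n = _check_cohort(trees)
    reps, weights = _dedupe(trees)
    workspaces = [workspace_for(t, cap=config.lattice_cap) for t in reps]
    exact_mask = [count_subtrees(t) <= config.subtree_threshold for t in reps]
    lam_s = config.sampling_rate
    theta = initial_theta(trees, n) if theta0 is None else theta0.copy()
    if support is not None:
        theta[~np.eye(n, dtype=bool) & ~support] = 0.0
    ss = np.random.SeedSequence(config.seed if config.seed is not None else 0)

    def observed_objective(th: np.ndarray) -> float | None:
        total = 0.0
        for ws, w, exact in zip(workspaces, weights, exact_mask):
            if not exact:
                return None
            total += w * np.log(ws.probability(th, lam_s))
        pen, _ = _penalty(th, config.gamma, config.l1_delta)
        return total - pen

    trace: list[float] = []
    obj0 = observed_objective(theta)
    if obj0 is not None:
        trace.append(obj0)
    converged = False
    deltas: list[float] = []
    it = 0
    for it in range(1, config.max_em_iters + 1):
        rng = np.random.default_rng(ss.spawn(1)[0])
        gaps = []
        for ws, exact in zip(workspaces, exact_mask):
            if exact:
                gaps.append(_estep_exact_ws(ws, theta, lam_s))
            else:
                gaps.append(
                    _estep_mc_ws(ws, theta, lam_s, config.mc_samples, rng)
                )
        theta_new = _mstep_arrays(
            workspaces, gaps, weights, config.gamma, config, theta, support
        )
        obj = observed_objective(theta_new)
        delta = float(np.max(np.abs(theta_new - theta)))
        deltas.append(delta)
        theta = theta_new
        if obj is not None:
            trace.append(obj)
            prev = trace[-2] if len(trace) >= 2 else None
            if prev is not None and abs(obj - prev) <= config.em_tol * (1.0 + abs(prev)):
                converged = True
                break
        else:
            # Monte-Carlo E-steps leave a noise floor under the parameter
            # updates, so convergence is a plateau: once the step size stops
            # shrinking relative to its recent history, more iterations only
            # resample the same stationary point.
            if delta <= config.em_tol * (1.0 + float(np.max(np.abs(theta)))):
                converged = True
                break
            if len(deltas) >= 6 and delta >= 0.9 * float(np.mean(deltas[-6:-1])):
                converged = True
                break
    theta_hat = _threshold(theta, config.zero_tol)
    return FitResult(
        theta=theta_hat,
        gamma=config.gamma,
        method="em",
        converged=converged,
        objective_trace=tuple(trace) if trace else (float("nan"),),
        n_iterations=it,
        tree_methods=tuple("exact" if e else "mc" for e in exact_mask),
    )


def fit(
    trees: Sequence[MutationTree],
    config: FitConfig | None = None,
    support: np.ndarray | None = None,
    theta0: np.ndarray | None = None,
) -> FitResult:
    """Fit a hazard network to a tree cohort.

    Dispatches on tree complexity: if the largest tree has at most
    ``config.subtree_threshold`` rooted subtrees, direct penalized MLE on the
    exact likelihood is used; otherwise the hybrid MC-EM algorithm.
    """
    config = config or FitConfig()
    _check_cohort(trees)
    max_subtrees = max(count_subtrees(t) for t in trees)
    if max_subtrees <= config.subtree_threshold:
        return fit_mle(trees, config, support=support, theta0=theta0)
    return fit_em(trees, config, support=support, theta0=theta0)
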