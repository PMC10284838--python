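"""Evolutionary trajectories: probabilities, waiting times, top-K search,
fixed-length distributions and KL divergence.

A sampling-terminated trajectory is an ordered sequence of distinct
mutations followed by the sampling event S.  Its probability is a product of
competing-exponential factors, one per step, each a rate divided by the
total rate (all pending mutations plus the sampling clock) out of the
current subclone; these probabilities sum to one over all trajectories.
Fixed-length trajectories drop the sampling clock and normalize over ordered
d-tuples instead, which makes distributions from different models directly
comparable via KL divergence.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import MHN, Path

__all__ = [
    "SampledTrajectory",
    "FixedLengthDistribution",
    "trajectory_probability",
    "trajectory_expected_time",
    "top_k_trajectories",
    "fixed_length_distribution",
    "kl_divergence",
    "trajectories_to_frame",
]

#: Guard on the number of ordered d-tuples enumerated, n! / (n-d)!.
FIXED_LENGTH_CAP = 1_000_000

KL_SMOOTHING = 1e-12


@dataclass(frozen=True)
class SampledTrajectory:
    """A trajectory terminated by the sampling event.

    ``path`` holds the mutation labels in order (the leading root and the
    trailing S are implicit).  ``expected_time`` is in units of
    ``1 / lambda_s``.
    """

    path: Path
    probability: float
    expected_time: float


def _check_path(mhn: MHN, path: Sequence[int]) -> Path:
    path = tuple(int(i) for i in path)
    if len(set(path)) != len(path):
        raise ValueError(f"trajectory {path} repeats a mutation")
    for i in path:
        if not (1 <= i <= mhn.n):
            raise ValueError(f"label {i} outside the range 1..{mhn.n}")
    return path


def _pending_rate_sum(mhn: MHN, prefix: Path) -> float:
    return sum(mhn.rate(prefix, j) for j in range(1, mhn.n + 1) if j not in prefix)


def trajectory_probability(mhn: MHN, path: Sequence[int]) -> float:
    """Probability of the sampling-terminated trajectory ``(0, path..., S)``.

    Product over steps of ``lambda_step / (lambda_s + sum of pending rates)``,
    times the terminal factor ``lambda_s / (lambda_s + sum of pending rates)``.
    """
    path = _check_path(mhn, path)
    lam_s = mhn.sampling_rate
    prob = 1.0
    prefix: Path = ()
    for sigma in path:
        total = lam_s + _pending_rate_sum(mhn, prefix)
        prob *= mhn.rate(prefix, sigma) / total
        prefix = prefix + (sigma,)
    prob *= lam_s / (lam_s + _pending_rate_sum(mhn, prefix))
    return prob


def trajectory_expected_time(mhn: MHN, path: Sequence[int]) -> float:
    """Expected waiting time of the trajectory, summed over its segments.

    Each segment of the race contributes the mean of the minimum of the
    pending exponential clocks, ``1 / (lambda_s + sum of pending rates)``,
    including the terminal segment ending in the sampling event.
    """
    path = _check_path(mhn, path)
    lam_s = mhn.sampling_rate
    total_time = 0.0
    prefix: Path = ()
    for sigma in path:
        total_time += 1.0 / (lam_s + _pending_rate_sum(mhn, prefix))
        prefix = prefix + (sigma,)
    total_time += 1.0 / (lam_s + _pending_rate_sum(mhn, prefix))
    return total_time


def top_k_trajectories(
    mhn: MHN, k: int, min_length: int = 1
) -> list[SampledTrajectory]:
    """The ``k`` most probable sampling-terminated trajectories.

    Best-first search over trajectory prefixes: a prefix's accumulated
    product of transition factors bounds the probability of any completion
    from above (every remaining factor is at most one), so prefixes popped in
    bound order cannot miss a better completion once ``k`` are settled.
    With ``min_length = 1`` the mutation-free trajectory ``(0, S)`` is
    excluded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    lam_s = mhn.sampling_rate
    done: list[tuple[float, Path]] = []  # (probability, path)
    # Heap of (-prefix_score, path); prefix_score is an admissible bound.
    heap: list[tuple[float, Path]] = [(-1.0, ())]
    while heap:
        neg_score, prefix = heapq.heappop(heap)
        score = -neg_score
        if len(done) >= k and sorted(done, reverse=True)[k - 1][0] >= score:
            break
        total = lam_s + _pending_rate_sum(mhn, prefix)
        if len(prefix) >= min_length:
            done.append((score * lam_s / total, prefix))
        for j in range(1, mhn.n + 1):
            if j not in prefix:
                heapq.heappush(
                    heap, (-(score * mhn.rate(prefix, j) / total), prefix + (j,))
                )
    done.sort(key=lambda t: (-t[0], t[1]))
    if len(done) < k:
        warnings.warn(
            f"only {len(done)} trajectories exist with at least "
            f"{min_length} mutation(s); returning all of them",
            stacklevel=2,
        )
    out = []
    for prob, path in done[:k]:
        out.append(
            SampledTrajectory(
                path=path,
                probability=prob,
                expected_time=trajectory_expected_time(mhn, path),
            )
        )
    return out


@dataclass(frozen=True)
class FixedLengthDistribution:
    """Probability distribution over ordered trajectories of exactly ``d`` mutations."""

    n: int
    d: int
    probabilities: Mapping[Path, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "probabilities", dict(self.probabilities))

    def __getitem__(self, path: Path) -> float:
        return self.probabilities[tuple(path)]

    def as_arrays(self) -> tuple[list[Path], np.ndarray]:
        keys = sorted(self.probabilities)
        return keys, np.array([self.probabilities[key] for key in keys])


def fixed_length_distribution(
    mhn: MHN, d: int, cap: int = FIXED_LENGTH_CAP
) -> FixedLengthDistribution:
    """Full distribution over ordered ``d``-tuples of distinct mutations.

    Competing exponentials without the sampling clock; the number of tuples
    is ``n! / (n-d)!`` and must not exceed ``cap``.
    """
    n = mhn.n
    if not (1 <= d <= n):
        raise ValueError(f"d must lie in 1..{n}")
    count = 1
    for m in range(n, n - d, -1):
        count *= m
    if count > cap:
        raise ValueError(
            f"{count} trajectories of length {d} exceed the cap of {cap}"
        )
    probs: dict[Path, float] = {}

    def recurse(prefix: Path, acc: float) -> None:
        if len(prefix) == d:
            probs[prefix] = acc
            return
        pending = [(j, mhn.rate(prefix, j)) for j in range(1, n + 1) if j not in prefix]
        total = sum(r for _, r in pending)
        for j, r in pending:
            recurse(prefix + (j,), acc * r / total)

    recurse((), 1.0)
    return FixedLengthDistribution(n=n, d=d, probabilities=probs)


def kl_divergence(
    p: FixedLengthDistribution,
    q: FixedLengthDistribution,
    smoothing: float = KL_SMOOTHING,
    strict: bool = False,
) -> float:
    """Kullback-Leibler divergence ``D(p || q)`` over fixed-length trajectories.

    Both distributions are mixed with the uniform distribution at weight
    ``smoothing`` before evaluation, so an estimated ``q`` that places zero
    mass on a feasible trajectory yields a finite value; ``strict = True``
    disables smoothing and raises on absolute continuity failures instead.
    Natural logarithm.
    """
    if (p.n, p.d) != (q.n, q.d):
        raise ValueError("distributions must share n and d")
    keys, pv = p.as_arrays()
    qv = np.array([q.probabilities.get(key, 0.0) for key in keys])
    if strict:
        if np.any((pv > 0) & (qv == 0)):
            raise ValueError("q has zero mass where p is positive")
        mask = pv > 0
        return float(np.sum(pv[mask] * np.log(pv[mask] / qv[mask])))
    k = len(keys)
    pv = (1.0 - smoothing) * pv + smoothing / k
    qv = (1.0 - smoothing) * qv + smoothing / k
    return float(np.sum(pv * np.log(pv / qv)))


def trajectories_to_frame(
    trajectories: Iterable[SampledTrajectory], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tabulate trajectories (arrow-joined paths) for TSV export."""

    def name(i: int) -> str:
        return labels[i - 1] if labels is not None else str(i)

    rows = [
        {
            "path": "->".join(["Root"] + [name(i) for i in t.path]),
            "probability": t.probability,
            "expected_time": t.expected_time,
        }
        for t in trajectories
    ]
    return pd.DataFrame(rows, columns=["path", "probability", "expected_time"])
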