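"""Next-event prediction given an observed tree.

Conditioned on a tree, the candidate next events are exactly the unobserved
events of the augmented tree, ``A(T) \\ T``.  By competing exponentials the
probability that a candidate happens first is its rate divided by the total
rate of all candidates.  Candidates are then ranked on a 0-100 percentile
scale with midranks for ties, which makes predictions comparable across
trees of different sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import MHN, MutationTree, Path, augment, enumerate_subtree_lattice

__all__ = [
    "NextEventTable",
    "FrequencyModel",
    "next_event_probabilities",
    "percentile_ranks",
    "retrospective_pairs",
    "retrospective_ranks",
    "forward_prediction",
    "ForwardPrediction",
    "baseline_models",
]


@dataclass(frozen=True)
class NextEventTable:
    """Candidate next events of a tree with rates, probabilities and ranks.

    ``events[k]`` is the full path of candidate ``k`` (parent path plus the
    new label); probabilities sum to one over the candidates.  Percentile
    ranks use the midrank convention, ``100 * (c_below + 0.5 * c_tie) / K``
    with ``c_tie`` counting the candidate's whole tie group.
    """

    tree: MutationTree
    events: tuple[Path, ...]
    rates: np.ndarray
    probabilities: np.ndarray

    @property
    def ranks(self) -> np.ndarray:
        return percentile_ranks(self.probabilities)

    def probability_of(self, event_path: Sequence[int]) -> float:
        return float(self.probabilities[self.events.index(tuple(event_path))])

    def rank_of(self, event_path: Sequence[int]) -> float:
        return float(self.ranks[self.events.index(tuple(event_path))])

    def to_frame(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        def name(i: int) -> str:
            return labels[i - 1] if labels is not None else str(i)

        ranks = self.ranks
        rows = [
            {
                "tree_id": self.tree.tree_id,
                "event": "->".join(["Root"] + [name(i) for i in ev]),
                "rate": float(self.rates[k]),
                "probability": float(self.probabilities[k]),
                "percentile_rank": float(ranks[k]),
            }
            for k, ev in enumerate(self.events)
        ]
        return pd.DataFrame(
            rows, columns=["tree_id", "event", "rate", "probability", "percentile_rank"]
        )


def percentile_ranks(probabilities: np.ndarray) -> np.ndarray:
    """Midrank percentiles on a 0-100 scale.

    The event with average rank ``r`` among ``K`` gets ``100 * (r - 0.5) / K``:
    a full tie group lands at 50, and with all-distinct values the largest
    probability gets ``100 * (K - 0.5) / K``.  Invariant under permutation
    and under positive rescaling of the probabilities.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.size == 0:
        raise ValueError("cannot rank an empty table")
    r = rankdata(probabilities, method="average")
    return 100.0 * (r - 0.5) / probabilities.size


def next_event_probabilities(mhn: MHN, tree: MutationTree) -> NextEventTable:
    """Competing-exponential probabilities of every addable event of ``tree``."""
    aug = augment(tree)
    events: list[Path] = []
    rates: list[float] = []
    for p, labels in sorted(aug.next_events.items()):
        for i in labels:
            events.append(p + (i,))
            rates.append(mhn.rate(p, i))
    if not events:
        raise ValueError(
            f"tree {tree.tree_id!r} is saturated: no addable next events"
        )
    rates_arr = np.array(rates)
    return NextEventTable(
        tree=tree,
        events=tuple(events),
        rates=rates_arr,
        probabilities=rates_arr / rates_arr.sum(),
    )


# ---------------------------------------------------------------------------
# Retrospective evaluation
# ---------------------------------------------------------------------------


def retrospective_pairs(
    tree: MutationTree, cap: int = 50_000
) -> list[tuple[MutationTree, Path]]:
    """All (rooted subtree, downstream event) pairs of a tree.

    For every rooted connected subtree ``S`` (the trivial root-only subtree
    included) and every node of the full tree whose parent lies in ``S`` but
    which is itself outside ``S``, emit the pair; the full tree has no
    boundary and contributes none.
    """
    lattice = enumerate_subtree_lattice(tree, cap=cap)
    pairs: list[tuple[MutationTree, Path]] = []
    for state in lattice.states:
        boundary = sorted(
            p for p in tree.paths if p and p not in state and p[:-1] in state
        )
        sub = MutationTree(
            n=tree.n, paths=frozenset(state), tree_id=tree.tree_id,
            patient_id=tree.patient_id,
        )
        pairs.extend((sub, v) for v in boundary)
    return pairs


def retrospective_ranks(mhn: MHN, tree: MutationTree, cap: int = 50_000) -> pd.DataFrame:
    """Percentile rank of every within-tree downstream event, per rooted subtree."""
    rows = []
    for sub, event in retrospective_pairs(tree, cap=cap):
        table = next_event_probabilities(mhn, sub)
        rows.append(
            {
                "tree_id": tree.tree_id,
                "subtree_size": sub.size,
                "event": "->".join(["Root"] + [str(i) for i in event]),
                "probability": table.probability_of(event),
                "percentile_rank": table.rank_of(event),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["tree_id", "subtree_size", "event", "probability", "percentile_rank"],
    )


# ---------------------------------------------------------------------------
# Forward evaluation on longitudinal tree pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ForwardPrediction:
    event: Path
    scoreable: bool
    probability: float | None = None
    percentile_rank: float | None = None


def forward_prediction(
    mhn: MHN, earlier_tree: MutationTree, later_tree: MutationTree
) -> list[ForwardPrediction]:
    """Score the new events of a later tree against the earlier tree.

    A new event (a node path of the later tree absent from the earlier one)
    is scoreable iff its parent path exists in the earlier tree, in which
    case its competing-exponential probability and percentile rank among all
    candidate next events of the earlier tree are reported; other new events
    are returned flagged unscoreable rather than dropped.
    """
    if earlier_tree.n != later_tree.n:
        raise ValueError("tree pair must share the mutation label set")
    new_events = sorted(
        p for p in later_tree.paths if p and p not in earlier_tree.paths
    )
    if not new_events:
        return []
    table = next_event_probabilities(mhn, earlier_tree)
    out = []
    for event in new_events:
        if event in table.events:
            out.append(
                ForwardPrediction(
                    event=event,
                    scoreable=True,
                    probability=table.probability_of(event),
                    percentile_rank=table.rank_of(event),
                )
            )
        else:
            out.append(ForwardPrediction(event=event, scoreable=False))
    return out


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyModel:
    """Cohort-frequency predictor of next events.

    The probability of a new event carrying mutation ``j`` is the chance of
    picking its placement node uniformly times the relative frequency of
    ``j`` among all mutation occurrences in the cohort, renormalized over the
    candidate events so the table sums to one.
    """

    n: int
    relative_frequency: np.ndarray

    def next_event_probabilities(self, tree: MutationTree) -> NextEventTable:
        from .model import augment as _augment

        aug = _augment(tree)
        n_nodes = len(tree.paths)
        events: list[Path] = []
        scores: list[float] = []
        for p, labels in sorted(aug.next_events.items()):
            for i in labels:
                events.append(p + (i,))
                scores.append(self.relative_frequency[i - 1] / n_nodes)
        if not events:
            raise ValueError(f"tree {tree.tree_id!r} is saturated")
        s = np.array(scores)
        total = s.sum()
        probs = s / total if total > 0 else np.full(len(s), 1.0 / len(s))
        return NextEventTable(
            tree=tree, events=tuple(events), rates=s, probabilities=probs
        )


def baseline_models(
    trees: Sequence[MutationTree], gamma: float = 0.5, **fit_kwargs
):
    """The two reference predictors: diagonal-only refit and cohort frequency.

    The first refits the hazard network with every off-diagonal pinned to
    zero (mutations independent, tree structure respected); the second is the
    :class:`FrequencyModel`.  Returns ``(diagonal_fit, frequency_model)``.
    """
    from .estimation import FitConfig, fit

    n = trees[0].n
    support = np.zeros((n, n), dtype=bool)
    diag_fit = fit(trees, FitConfig(gamma=gamma, **fit_kwargs), support=support)
    counts = np.zeros(n)
    for t in trees:
        for p in t.paths:
            if p:
                counts[p[-1] - 1] += 1
    total = counts.sum()
    rel = counts / total if total > 0 else np.full(n, 1.0 / n)
    return diag_fit, FrequencyModel(n=n, relative_frequency=rel)
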