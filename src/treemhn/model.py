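"""Core data model: hazard networks, mutation trees, augmented trees, subtree lattices.

A tumor mutation tree is a rooted tree whose non-root nodes carry mutation
labels from ``1..n``.  Every node is uniquely identified by the sequence of
mutation labels on its root-to-node path (its *subclone* / *trajectory
prefix*), because siblings carry pairwise distinct labels.  Internally a tree
is therefore stored as a prefix-closed set of label tuples, with the empty
tuple ``()`` standing for the root (the wild type, written ``0`` in files).

The hazard network :class:`MHN` is an ``n x n`` matrix of log-hazards
``theta``.  Diagonal entries are baseline log-rates of the mutations;
off-diagonal entry ``theta[i, j]`` is the multiplicative (on log scale)
effect of an ancestor mutation ``j + 1`` on the rate of mutation ``i + 1``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "MHN",
    "MutationTree",
    "AugmentedTree",
    "SubtreeLattice",
    "TreeValidationError",
    "SubtreeCapError",
    "augment",
    "count_subtrees",
    "enumerate_subtree_lattice",
    "DEFAULT_LATTICE_CAP",
]

#: Memory guard on the number of rooted subtrees enumerated for one tree.
DEFAULT_LATTICE_CAP = 50_000

#: Log-rates are clipped here before exponentiation (overflow guard).
LOG_RATE_CAP = 30.0

Path = tuple[int, ...]


class TreeValidationError(ValueError):
    """An input tree violates a structural invariant."""


class SubtreeCapError(RuntimeError):
    """A tree has more rooted subtrees than the configured cap allows."""


# ---------------------------------------------------------------------------
# Mutual Hazard Network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MHN:
    """A Mutual Hazard Network: ``n x n`` log-hazard matrix plus sampling rate.

    Parameters
    ----------
    theta
        Square matrix of finite log-hazards.  ``theta[i, i]`` is the baseline
        log-rate of mutation ``i + 1``; ``theta[i, j]`` (``i != j``) the
        promoting (positive) or inhibiting (negative) effect of mutation
        ``j + 1`` on mutation ``i + 1``.
    sampling_rate
        Rate ``lambda_s`` of the independent exponential sampling event.
        Fixed to 1 by default for identifiability.
    labels
        Optional gene names for the mutations, index ``i`` naming mutation
        ``i + 1``.
    """

    theta: np.ndarray
    sampling_rate: float = 1.0
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if theta.ndim != 2 or theta.shape[0] != theta.shape[1]:
            raise ValueError(f"theta must be a square matrix, got shape {theta.shape}")
        if not np.all(np.isfinite(theta)):
            raise ValueError("theta entries must be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.labels is not None and len(self.labels) != theta.shape[0]:
            raise ValueError("labels length must equal n")
        object.__setattr__(self, "theta", theta)

    @property
    def n(self) -> int:
        """Number of mutations."""
        return self.theta.shape[0]

    def log_rate(self, path: Sequence[int], i: int) -> float:
        """Log-hazard ``theta_ii + sum_{j in path} theta_ij`` of event ``(path, i)``."""
        self._check_event(path, i)
        k = i - 1
        s = self.theta[k, k]
        for j in path:
            s += self.theta[k, j - 1]
        return min(float(s), LOG_RATE_CAP)

    def rate(self, path: Sequence[int], i: int) -> float:
        """Hazard of mutation ``i`` arising in the subclone ``path``.

        Competing-exponential rate ``Theta_ii * prod_{j in path} Theta_ij``,
        multiplicative in the ancestor effects; equals ``Theta_ii`` at the
        root (empty path).
        """
        return float(np.exp(self.log_rate(path, i)))

    def _check_event(self, path: Sequence[int], i: int) -> None:
        if not (1 <= i <= self.n):
            raise ValueError(f"mutation {i} outside the label range 1..{self.n}")
        if i in path:
            raise ValueError(f"mutation {i} already present on the path {tuple(path)}")
        for j in path:
            if not (1 <= j <= self.n):
                raise ValueError(f"path label {j} outside the range 1..{self.n}")

    def with_theta(self, theta: np.ndarray) -> "MHN":
        return MHN(theta=theta, sampling_rate=self.sampling_rate, labels=self.labels)


# ---------------------------------------------------------------------------
# Mutation trees
# ---------------------------------------------------------------------------


def _validate_paths(n: int, paths: frozenset[Path]) -> None:
    if () not in paths:
        raise TreeValidationError("tree has no root (empty path missing)")
    for p in paths:
        if len(set(p)) != len(p):
            raise TreeValidationError(
                f"mutation repeated along the lineage {p}: labels on a "
                "root-to-node path must be pairwise distinct"
            )
        for j in p:
            if not (1 <= j <= n):
                raise TreeValidationError(f"label {j} on path {p} outside range 1..{n}")
        if p and p[:-1] not in paths:
            raise TreeValidationError(f"node {p} is disconnected: parent {p[:-1]} missing")


@dataclass(frozen=True)
class MutationTree:
    """A rooted tumor mutation tree over a cohort-wide label set ``1..n``.

    ``paths`` is the prefix-closed set of root-to-node label sequences; the
    root is the empty tuple.  The same mutation label may appear in different
    branches (parallel mutations), but never twice on one lineage and never on
    two sibling edges.  Equality and hashing use this canonical path-set form.
    """

    n: int
    paths: frozenset[Path]
    tree_id: str = ""
    patient_id: str = ""
    weight: float = 1.0

    def __post_init__(self) -> None:
        paths = frozenset(tuple(p) for p in self.paths)
        _validate_paths(self.n, paths)
        object.__setattr__(self, "paths", paths)

    @classmethod
    def from_paths(
        cls,
        n: int,
        paths: Iterable[Sequence[int]],
        tree_id: str = "",
        patient_id: str = "",
        weight: float = 1.0,
    ) -> "MutationTree":
        return cls(
            n=n,
            paths=frozenset(tuple(p) for p in paths) | {()},
            tree_id=tree_id,
            patient_id=patient_id,
            weight=weight,
        )

    @classmethod
    def from_edges(
        cls,
        n: int,
        nodes: Iterable[tuple[object, int, object]],
        tree_id: str = "",
        patient_id: str = "",
        weight: float = 1.0,
    ) -> "MutationTree":
        """Build a tree from ``(node_id, mutation_label, parent_id)`` records.

        The root row carries label 0 and is its own parent (self-loop
        convention common in tree-cohort CSVs).
        """
        records = list(nodes)
        by_id: dict[object, tuple[int, object]] = {}
        for node_id, label, parent_id in records:
            if node_id in by_id:
                raise TreeValidationError(
                    f"tree {tree_id!r}: duplicate node id {node_id!r}"
                )
            by_id[node_id] = (int(label), parent_id)
        roots = [nid for nid, (lab, pid) in by_id.items() if lab == 0 and pid == nid]
        if len(roots) != 1:
            raise TreeValidationError(
                f"tree {tree_id!r}: expected exactly one root row "
                f"(label 0, its own parent), found {len(roots)}"
            )
        root = roots[0]
        # Resolve each node's path to the root, detecting orphans and cycles.
        path_of: dict[object, Path] = {root: ()}

        def resolve(nid: object, seen: set[object]) -> Path:
            if nid in path_of:
                return path_of[nid]
            if nid not in by_id:
                raise TreeValidationError(
                    f"tree {tree_id!r}: node {nid!r} has no row (orphan)"
                )
            if nid in seen:
                raise TreeValidationError(f"tree {tree_id!r}: cycle through node {nid!r}")
            seen.add(nid)
            label, parent = by_id[nid]
            if label == 0:
                raise TreeValidationError(
                    f"tree {tree_id!r}: non-root node {nid!r} carries label 0"
                )
            parent_path = resolve(parent, seen)
            p = parent_path + (label,)
            path_of[nid] = p
            return p

        sib: dict[tuple[Path, int], object] = {}
        for nid in by_id:
            p = resolve(nid, set())
            if p:
                key = (p[:-1], p[-1])
                if key in sib and sib[key] != nid:
                    raise TreeValidationError(
                        f"tree {tree_id!r}: nodes {sib[key]!r} and {nid!r} are "
                        f"siblings with the same mutation label {p[-1]}"
                    )
                sib[key] = nid
        return cls.from_paths(
            n, path_of.values(), tree_id=tree_id, patient_id=patient_id, weight=weight
        )

    # -- structure queries --------------------------------------------------

    @property
    def nodes(self) -> list[Path]:
        """All node paths in canonical order (by depth, then lexicographic)."""
        return sorted(self.paths, key=lambda p: (len(p), p))

    @property
    def size(self) -> int:
        """Number of non-root nodes (observed mutational events)."""
        return len(self.paths) - 1

    def children(self, path: Path) -> list[Path]:
        d = len(path) + 1
        return sorted(p for p in self.paths if len(p) == d and p[:-1] == path)

    def mutations(self) -> set[int]:
        """Set of mutation labels occurring anywhere in the tree."""
        return {p[-1] for p in self.paths if p}

    def subtree_paths(self, path: Path) -> set[Path]:
        """All node paths at or below ``path``."""
        d = len(path)
        return {p for p in self.paths if p[:d] == path}

    def canonical(self) -> tuple[Path, ...]:
        return tuple(self.nodes)

    def relabeled(self, **meta) -> "MutationTree":
        kw = dict(
            n=self.n,
            paths=self.paths,
            tree_id=self.tree_id,
            patient_id=self.patient_id,
            weight=self.weight,
        )
        kw.update(meta)
        return MutationTree(**kw)


# ---------------------------------------------------------------------------
# Augmented trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AugmentedTree:
    """An observed tree plus every event that could occur next.

    ``next_events`` maps each node path of the base tree to the sorted tuple
    of mutation labels that are absent from the node's lineage and not
    already observed as children — the events "right after sampling".
    """

    base: MutationTree
    next_events: Mapping[Path, tuple[int, ...]]

    def events(self) -> Iterator[tuple[Path, int, bool]]:
        """Yield every event ``(parent_path, label, observed)`` of the augmented tree."""
        for p in self.base.nodes:
            observed = {c[-1] for c in self.base.children(p)}
            on_path = set(p)
            for i in range(1, self.base.n + 1):
                if i not in on_path:
                    yield p, i, i in observed

    def unobserved_events(self) -> list[tuple[Path, int]]:
        return [(p, i) for p, labels in sorted(self.next_events.items()) for i in labels]


def augment(tree: MutationTree) -> AugmentedTree:
    """Attach to every node the set of addable next events ``A(T) \\ T``."""
    next_events: dict[Path, tuple[int, ...]] = {}
    for p in tree.nodes:
        observed = {c[-1] for c in tree.children(p)}
        on_path = set(p)
        next_events[p] = tuple(
            i for i in range(1, tree.n + 1) if i not in on_path and i not in observed
        )
    return AugmentedTree(base=tree, next_events=next_events)


# ---------------------------------------------------------------------------
# Subtree counting and lattice enumeration
# ---------------------------------------------------------------------------


def count_subtrees(tree: MutationTree) -> int:
    """Number of rooted connected subtrees of ``tree`` containing the root.

    Computed by the product recursion ``count(v) = prod_c (1 + count(c))``
    over the children ``c`` of ``v``; a leaf counts 1.
    """

    def count(path: Path) -> int:
        total = 1
        for c in tree.children(path):
            total *= 1 + count(c)
        return total

    return count(())


@dataclass(frozen=True)
class SubtreeLattice:
    """Rooted subtrees of a tree, ordered by a linear extension of inclusion.

    ``states[0]`` is the root-only subtree and ``states[-1]`` the full tree;
    states are sorted by non-decreasing size, so any containment goes from an
    earlier state to a later one.
    """

    tree: MutationTree
    states: tuple[frozenset[Path], ...]

    def __len__(self) -> int:
        return len(self.states)

    @property
    def index(self) -> dict[frozenset[Path], int]:
        return {s: k for k, s in enumerate(self.states)}


def enumerate_subtree_lattice(
    tree: MutationTree, cap: int = DEFAULT_LATTICE_CAP
) -> SubtreeLattice:
    """Enumerate all rooted subtrees, subsets before supersets.

    Raises
    ------
    SubtreeCapError
        If the tree has more than ``cap`` rooted subtrees; such trees should
        take the Monte-Carlo EM path instead of exact enumeration.
    """
    total = count_subtrees(tree)
    if total > cap:
        raise SubtreeCapError(
            f"tree {tree.tree_id!r} has {total} rooted subtrees, above the cap "
            f"of {cap}; use the Monte-Carlo EM path for this tree"
        )

    def subtrees(path: Path) -> list[frozenset[Path]]:
        # Subtrees of the branch at `path` that contain `path` itself.
        options_per_child = []
        for c in tree.children(path):
            child_sets = subtrees(c)
            options_per_child.append([frozenset()] + child_sets)
        out = []
        for combo in itertools.product(*options_per_child):
            s = frozenset({path}).union(*combo) if combo else frozenset({path})
            out.append(s)
        return out

    states = subtrees(())
    states.sort(key=lambda s: (len(s), tuple(sorted(s))))
    return SubtreeLattice(tree=tree, states=tuple(states))
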