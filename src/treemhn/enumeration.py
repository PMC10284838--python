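"""Exhaustive enumeration utilities for small problem sizes.

These brute-force generators are meant for validation: summing exact tree
probabilities to one, cross-checking best-first trajectory search, and
similar oracle comparisons.  They scale factorially and are capped at small
``n``.
"""

from __future__ import annotations

import itertools

from .model import MutationTree, Path

__all__ = ["enumerate_all_trees", "enumerate_sampled_trajectories"]

MAX_ENUM_N = 4


def enumerate_all_trees(n: int) -> list[MutationTree]:
    """All valid mutation trees on labels ``1..n`` (including the root-only tree).

    Generated by breadth-first closure under single-event additions: starting
    from the root-only tree, repeatedly attach any mutation absent from a
    node's lineage and from its current children.  Capped at ``n <= 4``.
    """
    if n > MAX_ENUM_N:
        raise ValueError(f"exhaustive tree enumeration is capped at n <= {MAX_ENUM_N}")
    seen: set[frozenset[Path]] = set()
    frontier = [frozenset({()})]
    seen.add(frontier[0])
    while frontier:
        nxt = []
        for paths in frontier:
            for p in paths:
                on_path = set(p)
                children = {q[-1] for q in paths if q[:-1] == p and len(q) == len(p) + 1}
                for i in range(1, n + 1):
                    if i in on_path or i in children:
                        continue
                    grown = paths | {p + (i,)}
                    if grown not in seen:
                        seen.add(grown)
                        nxt.append(grown)
        frontier = nxt
    return [MutationTree(n=n, paths=paths) for paths in sorted(seen, key=sorted)]


def enumerate_sampled_trajectories(n: int, min_length: int = 0) -> list[Path]:
    """All sampling-terminated trajectories ``(sigma_1, ..., sigma_d)``, d >= min_length.

    The terminal sampling event is implicit; the root prefix 0 is omitted as
    everywhere in this package.
    """
    out: list[Path] = []
    for d in range(min_length, n + 1):
        out.extend(itertools.permutations(range(1, n + 1), d))
    return out
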