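"""Readers and writers for tree cohorts and hazard networks.

The canonical cohort interchange is a CSV edge list with one row per node
and columns ``Patient_ID, Tree_ID, Node_ID, Mutation_ID, Parent_ID``; the
root row of each tree carries ``Mutation_ID`` 0 and is its own parent.  A
nested-JSON dialect and an integer-to-gene-symbol label map are also
supported.  Networks travel as square CSV matrices of log-hazards with a
``#``-commented metadata block.
"""

from __future__ import annotations

import json
from pathlib import Path as FsPath
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import MHN, MutationTree, TreeValidationError

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_cohort_json",
    "write_cohort_json",
    "read_network",
    "write_network",
    "read_label_map",
    "write_label_map",
]

COHORT_COLUMNS = ["Patient_ID", "Tree_ID", "Node_ID", "Mutation_ID", "Parent_ID"]


def read_cohort(
    path: str | FsPath, n: int | None = None
) -> tuple[list[MutationTree], dict[int, str]]:
    """Load a cohort CSV; returns validated trees and the (possibly empty) label map.

    ``n`` defaults to the maximum mutation label seen in the file.  A label
    map sidecar named ``<stem>.labels.csv`` next to the cohort file is picked
    up automatically when present.
    """
    path = FsPath(path)
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks columns {missing}")
    sidecar = path.with_suffix(".labels.csv")
    label_map = read_label_map(sidecar) if sidecar.exists() else {}
    if n is None:
        labels = df["Mutation_ID"].astype(int)
        n = int(labels.max()) if len(labels) else 0
        if label_map:
            n = max(n, max(label_map))
    trees = []
    for (patient_id, tree_id), grp in df.groupby(["Patient_ID", "Tree_ID"], sort=True):
        records = [
            (row.Node_ID, int(row.Mutation_ID), row.Parent_ID)
            for row in grp.itertuples()
        ]
        trees.append(
            MutationTree.from_edges(
                n, records, tree_id=str(tree_id), patient_id=str(patient_id)
            )
        )
    return trees, label_map


def write_cohort(
    trees: Sequence[MutationTree],
    path: str | FsPath,
    label_map: Mapping[int, str] | None = None,
) -> None:
    rows = []
    for t in trees:
        ids = {p: k for k, p in enumerate(t.nodes)}
        for p, node_id in ids.items():
            rows.append(
                {
                    "Patient_ID": t.patient_id or t.tree_id or "P",
                    "Tree_ID": t.tree_id or "T",
                    "Node_ID": node_id,
                    "Mutation_ID": p[-1] if p else 0,
                    "Parent_ID": ids[p[:-1]] if p else node_id,
                }
            )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)
    if label_map:
        write_label_map(label_map, FsPath(path).with_suffix(".labels.csv"))


def _tree_to_nested(tree: MutationTree) -> dict:
    def node(path):
        return {
            "mutation": path[-1] if path else 0,
            "children": [node(c) for c in tree.children(path)],
        }

    return {
        "patient_id": tree.patient_id,
        "tree_id": tree.tree_id,
        "root": node(()),
    }


def _nested_to_paths(node: dict, prefix: tuple[int, ...], out: set) -> None:
    out.add(prefix)
    for child in node.get("children", []):
        _nested_to_paths(child, prefix + (int(child["mutation"]),), out)


def write_cohort_json(
    trees: Sequence[MutationTree],
    path: str | FsPath,
    label_map: Mapping[int, str] | None = None,
) -> None:
    payload = {
        "n": trees[0].n if trees else 0,
        "labels": {str(k): v for k, v in (label_map or {}).items()},
        "trees": [_tree_to_nested(t) for t in trees],
    }
    FsPath(path).write_text(json.dumps(payload, indent=1))


def read_cohort_json(path: str | FsPath) -> tuple[list[MutationTree], dict[int, str]]:
    payload = json.loads(FsPath(path).read_text())
    n = int(payload["n"])
    label_map = {int(k): v for k, v in payload.get("labels", {}).items()}
    trees = []
    for t in payload["trees"]:
        paths: set = set()
        root = t["root"]
        if int(root.get("mutation", 0)) != 0:
            raise TreeValidationError(f"tree {t.get('tree_id')!r}: root must carry label 0")
        _nested_to_paths(root, (), paths)
        trees.append(
            MutationTree.from_paths(
                n, paths, tree_id=str(t.get("tree_id", "")),
                patient_id=str(t.get("patient_id", "")),
            )
        )
    return trees, label_map


def read_label_map(path: str | FsPath) -> dict[int, str]:
    df = pd.read_csv(path)
    return {int(row.Mutation_ID): str(row.Label) for row in df.itertuples()}


def write_label_map(label_map: Mapping[int, str], path: str | FsPath) -> None:
    pd.DataFrame(
        [{"Mutation_ID": k, "Label": v} for k, v in sorted(label_map.items())]
    ).to_csv(path, index=False)


def write_network(
    mhn: MHN, path: str | FsPath, metadata: Mapping[str, object] | None = None
) -> None:
    """Write the log-hazard matrix as CSV with a commented metadata block."""
    labels = list(mhn.labels) if mhn.labels else [str(i + 1) for i in range(mhn.n)]
    lines = [f"# sampling_rate={mhn.sampling_rate!r}"]
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}={value!r}")
    df = pd.DataFrame(mhn.theta, columns=labels)
    FsPath(path).write_text("\n".join(lines) + "\n" + df.to_csv(index=False))


def read_network(path: str | FsPath) -> tuple[MHN, dict[str, str]]:
    path = FsPath(path)
    metadata: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if not line.startswith("#"):
            break
        key, _, value = line.lstrip("# ").partition("=")
        metadata[key.strip()] = value.strip().strip("'\"")
    df = pd.read_csv(path, comment="#")
    theta = df.to_numpy(dtype=float)
    sampling_rate = float(metadata.get("sampling_rate", 1.0))
    return (
        MHN(theta=theta, sampling_rate=sampling_rate, labels=tuple(df.columns)),
        metadata,
    )
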