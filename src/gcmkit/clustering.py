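"""Hierarchical clustering of the point map into cluster solutions.

Following GCM convention, clusters are formed from the 2-D map
coordinates, not from the similarity matrix directly: Ward agglomeration
on Euclidean distances yields a merge tree, and a k-cluster solution is
read off by undoing the top k-1 merges.  Cluster ids are stable (numbered
1..k in order of each cluster's lowest member statement id) so that
solutions from different runs line up.  An expert group may then move
individual statements between clusters; such moves are recorded in the
solution's provenance.

Bridging values quantify how consistently a statement was sorted with its
map neighbours: the raw value is the co-sort-weighted mean map distance
from the statement to all others, min-max normalized across statements to
[0, 1].  Low bridging means the statement was grouped with nearby
statements; high bridging means its co-sorts span the map.  The exact
index computed by proprietary GCM software is unpublished; this weighted
mean-distance form matches its documented range and interpretation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage

from .point_map import PointMap
from .similarity import SimilarityMatrix


@dataclass(frozen=True)
class MergeTree:
    """Agglomeration history: scipy-style (left, right, height, size) rows."""

    merges: np.ndarray  # (S-1) x 4 linkage matrix
    ids: tuple[int, ...]

    def __post_init__(self) -> None:
        h = self.merges[:, 2]
        if np.any(np.diff(h) < -1e-12):
            raise ValueError("merge heights must be nondecreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class ClusterSolution:
    """Statement -> cluster assignment with labels and provenance."""

    k: int
    assignment: Mapping[int, int]  # statement_id -> cluster_id
    labels: Mapping[int, str]  # cluster_id -> display label
    provenance: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        cids = set(self.assignment.values())
        if len(cids) != self.k:
            raise ValueError(
                f"solution declares k={self.k} but has {len(cids)} nonempty clusters"
            )
        if set(self.labels) != cids:
            raise ValueError("labels must cover exactly the cluster ids")

    def members(self, cluster_id: int) -> tuple[int, ...]:
        return tuple(
            sorted(s for s, c in self.assignment.items() if c == cluster_id)
        )

    @property
    def cluster_ids(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.assignment.values())))

    def label_to_id(self) -> dict[str, int]:
        return {lab: cid for cid, lab in self.labels.items()}


@dataclass(frozen=True)
class BridgingResult:
    """Per-statement bridging in [0, 1] plus per-cluster means."""

    values: Mapping[int, float]  # statement_id -> normalized bridging
    raw: Mapping[int, float]
    cluster_means: Mapping[int, float]  # empty if no solution supplied
    isolated: tuple[int, ...]  # statements with no surviving co-sorts


def ward_tree(pm: PointMap) -> MergeTree:
    """Ward agglomeration of the map coordinates (Euclidean distances)."""
    if len(pm.ids) < 2:
        raise ValueError("clustering requires at least 2 statements")
    Z = linkage(pm.coordinates, method="ward")
    return MergeTree(Z, pm.ids)


def cut_to_solution(
    tree: MergeTree,
    k: int,
    labels: Mapping[int, str] | None = None,
) -> ClusterSolution:
    """Cut the tree into exactly k clusters by undoing the top k-1 merges.

    Cluster ids are 1..k assigned in order of each cluster's lowest member
    statement id.  ``labels`` may override the default "Cluster n" labels.
    """
    S = tree.n_leaves
    if not 1 <= k <= S:
        raise ValueError(f"k={k} outside [1, {S}]")
    flat = cut_tree(tree.merges, n_clusters=k).ravel()
    # relabel by lowest member statement id for stability
    groups: dict[int, list[int]] = {}
    for sid, g in zip(tree.ids, flat):
        groups.setdefault(int(g), []).append(sid)
    ordered = sorted(groups.values(), key=min)
    assignment = {sid: cid for cid, members in enumerate(ordered, 1) for sid in members}
    final_labels = {cid: f"Cluster {cid}" for cid in range(1, k + 1)}
    if labels:
        final_labels.update({int(c): str(l) for c, l in labels.items()})
    return ClusterSolution(
        k=k,
        assignment=assignment,
        labels=final_labels,
        provenance=(f"cut ward tree at k={k}",),
    )


def apply_moves(
    solution: ClusterSolution,
    moves: Sequence[tuple[int, int | str]],
) -> ClusterSolution:
    """Reassign statements to target clusters (by id or label).

    Mirrors the expert-review step in which a small number of statements
    are moved to a better-fitting cluster.  A move that would empty its
    source cluster is an error: the solution must keep exactly k nonempty
    clusters.
    """
    assignment = dict(solution.assignment)
    by_label = solution.label_to_id()
    provenance = list(solution.provenance)
    for sid, target in moves:
        if sid not in assignment:
            raise KeyError(f"unknown statement id {sid}")
        if isinstance(target, str):
            if target not in by_label:
                raise KeyError(f"unknown cluster label {target!r}")
            target_id = by_label[target]
        else:
            if target not in solution.labels:
                raise KeyError(f"unknown cluster id {target}")
            target_id = int(target)
        source = assignment[sid]
        if source == target_id:
            provenance.append(f"move {sid}: already in cluster {target_id} (no-op)")
            continue
        if sum(1 for c in assignment.values() if c == source) == 1:
            raise ValueError(
                f"moving statement {sid} would empty cluster {source} "
                f"({solution.labels[source]!r})"
            )
        assignment[sid] = target_id
        provenance.append(
            f"move {sid}: {solution.labels[source]!r} -> {solution.labels[target_id]!r}"
        )
    return replace(
        solution, assignment=assignment, provenance=tuple(provenance)
    )


def reference_expert_moves() -> list[tuple[int, str]]:
    """The three expert moves from the depression-treatment study,
    expressed against cluster labels: mutual respect (17) to the
    client-clinician interaction cluster, and trigger evaluation (48) and
    comorbidity treatment (36) to the good-practice cluster."""
    return [
        (17, "Interaction client clinician"),
        (48, "Clinician's adherence to good practice"),
        (36, "Clinician's adherence to good practice"),
    ]


def bridging_values(
    pm: PointMap,
    T: SimilarityMatrix,
    solution: ClusterSolution | None = None,
) -> BridgingResult:
    """Co-sort-weighted mean map distance per statement, scaled to [0, 1].

    raw_i = sum_{j != i} T_ij * dist(i, j) / sum_{j != i} T_ij.  A
    statement whose co-sort counts were all removed by the cut-off has no
    weights; it receives its unweighted mean distance to all other
    statements and is flagged as isolated.  Raw values are min-max
    normalized; if all raw values coincide, every statement gets 0.
    """
    if pm.ids != T.ids:
        raise ValueError("point map and similarity matrix index different statements")
    dist = pm.distances()
    W = T.matrix.astype(float).copy()
    np.fill_diagonal(W, 0.0)
    raw = np.empty(len(pm.ids))
    isolated: list[int] = []
    n = len(pm.ids)
    for i in range(n):
        wsum = W[i].sum()
        if wsum == 0:
            raw[i] = dist[i].sum() / (n - 1)
            isolated.append(pm.ids[i])
        else:
            raw[i] = float(W[i] @ dist[i]) / wsum
    span = raw.max() - raw.min()
    # a span at floating-point noise level means "all raw values equal"
    if span <= 1e-9 * max(1.0, abs(raw.max())):
        norm = np.zeros_like(raw)
    else:
        norm = (raw - raw.min()) / span
    values = dict(zip(pm.ids, norm.tolist()))
    cluster_means: dict[int, float] = {}
    if solution is not None:
        for cid in solution.cluster_ids:
            members = solution.members(cid)
            cluster_means[cid] = float(np.mean([values[s] for s in members]))
    return BridgingResult(
        values=values,
        raw=dict(zip(pm.ids, raw.tolist())),
        cluster_means=cluster_means,
        isolated=tuple(isolated),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_clusters(
    solution: ClusterSolution,
    path: str | Path,
    bridging: BridgingResult | None = None,
) -> None:
    rows = []
    for sid in sorted(solution.assignment):
        cid = solution.assignment[sid]
        rows.append(
            {
                "statement_id": sid,
                "cluster_id": cid,
                "cluster_label": solution.labels[cid],
                "bridging": "" if bridging is None else round(bridging.values[sid], 6),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def read_moves(path: str | Path) -> list[tuple[int, str]]:
    """Read ``statement_id,target_cluster_label`` move lists."""
    df = pd.read_csv(path, dtype=str, encoding="utf-8")
    expected = ["statement_id", "target_cluster_label"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: columns must be {expected}")
    return [(int(r.statement_id), r.target_cluster_label) for r in df.itertuples()]


def write_tree(tree: MergeTree, path: str | Path) -> None:
    payload = {
        "leaves": list(tree.ids),
        "merges": [
            {"left": int(l), "right": int(r), "height": float(h), "size": int(s)}
            for l, r, h, s in tree.merges
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
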