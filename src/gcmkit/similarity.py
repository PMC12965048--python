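"""Co-sort similarity matrices and the dissimilarity transform for scaling.

Each accepted sorter contributes a binary statement-by-statement co-sort
matrix (1 when two statements share a pile).  Summing over sorters gives
the group similarity matrix T, whose entry T_ij counts how many sorters
grouped i with j.  A cut-off discards weak agreements (entries at or below
the threshold are zeroed; with the conventional cut-off of 1, a pair
grouped by a single sorter is not taken into account).  The dissimilarity
D_ij = 1 - T_ij / n_sorters feeds the multidimensional scaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import SchemaError, SortRecord, StatementSet


@dataclass(frozen=True)
class CosortMatrix:
    """One sorter's binary co-pile indicator matrix (block-diagonal up to
    statement order; the co-pile relation is an equivalence relation)."""

    matrix: np.ndarray
    ids: tuple[int, ...]
    participant_id: str


@dataclass(frozen=True)
class SimilarityMatrix:
    """Group-level integer co-sort counts over n_sorters accepted sorts."""

    matrix: np.ndarray
    ids: tuple[int, ...]
    n_sorters: int
    cutoff: int | None = None  # None = raw counts, else the applied cut-off

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise ValueError("similarity matrix shape does not match ids")
        if not np.array_equal(m, m.T):
            raise ValueError("similarity matrix must be symmetric")


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric dissimilarities in [0, 1] with zero diagonal."""

    matrix: np.ndarray
    ids: tuple[int, ...]
    n_sorters: int

    def __post_init__(self) -> None:
        m = self.matrix
        if not np.array_equal(m, m.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("dissimilarity diagonal must be zero")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("dissimilarities must lie in [0, 1]")


def cosort_matrix(sort: SortRecord, statements: StatementSet) -> CosortMatrix:
    """Binary same-pile indicator for one complete sort. Diagonal is 1."""
    if not sort.is_complete(statements):
        missing = sorted(set(statements.ids) - sort.sorted_ids)
        raise ValueError(
            f"sort {sort.participant_id!r} is incomplete (missing {missing})"
        )
    ids = tuple(sorted(statements.ids))
    index = {sid: k for k, sid in enumerate(ids)}
    m = np.zeros((len(ids), len(ids)), dtype=np.int64)
    for _, members in sort.piles:
        idx = [index[s] for s in members]
        m[np.ix_(idx, idx)] = 1
    return CosortMatrix(m, ids, sort.participant_id)


def group_similarity(
    sorts: Sequence[SortRecord], statements: StatementSet
) -> SimilarityMatrix:
    """Sum of per-sorter co-sort matrices; order of sorters is immaterial."""
    if not sorts:
        raise ValueError("group similarity requires at least one accepted sort")
    total = None
    for rec in sorts:
        c = cosort_matrix(rec, statements).matrix
        total = c if total is None else total + c
    ids = tuple(sorted(statements.ids))
    return SimilarityMatrix(total, ids, n_sorters=len(sorts))


def apply_cutoff(T: SimilarityMatrix, cutoff: int) -> SimilarityMatrix:
    """Zero off-diagonal counts at or below the cut-off.

    A cut-off of 1 removes pairs grouped together by only a single sorter;
    0 leaves the matrix unchanged.  The diagonal is untouched.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    if cutoff >= T.n_sorters:
        raise ValueError(
            f"cutoff {cutoff} >= n_sorters {T.n_sorters} would zero all agreements"
        )
    m = T.matrix.copy()
    off = ~np.eye(m.shape[0], dtype=bool)
    m[off & (m <= cutoff)] = 0
    return SimilarityMatrix(m, T.ids, T.n_sorters, cutoff=cutoff)


def to_dissimilarity(T: SimilarityMatrix) -> DissimilarityMatrix:
    """D_ij = 1 - T_ij / n_sorters, with a hard zero diagonal."""
    if T.n_sorters <= 0:
        raise ValueError("n_sorters must be positive")
    d = 1.0 - T.matrix.astype(float) / T.n_sorters
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    return DissimilarityMatrix(d, T.ids, T.n_sorters)


# ---------------------------------------------------------------------------
# Serialization: square matrices with statement-id header row and column
# ---------------------------------------------------------------------------


def write_matrix(
    matrix: SimilarityMatrix | DissimilarityMatrix, path: str | Path
) -> None:
    df = pd.DataFrame(matrix.matrix, index=matrix.ids, columns=matrix.ids)
    df.index.name = "statement_id"
    df.to_csv(path, encoding="utf-8")


def read_similarity(path: str | Path, n_sorters: int) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0, encoding="utf-8")
    ids = tuple(int(c) for c in df.columns)
    if tuple(int(i) for i in df.index) != ids:
        raise SchemaError(f"{path}: header row and column ids disagree")
    return SimilarityMatrix(df.to_numpy(dtype=np.int64), ids, n_sorters)


def similarity_manifest(T: SimilarityMatrix) -> dict:
    """Provenance entry recorded alongside serialized matrices."""
    return {
        "n_sorters": T.n_sorters,
        "cutoff": T.cutoff,
        "transform": "1 - T/n_sorters",
        "n_statements": len(T.ids),
    }


def write_manifest_entry(T: SimilarityMatrix, path: str | Path) -> None:
    Path(path).write_text(json.dumps(similarity_manifest(T), indent=2))
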