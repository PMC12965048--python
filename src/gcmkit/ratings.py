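"""Importance-rating statistics at statement and cluster level.

Per-statement statistics are available-case: each mean uses every rating
actually given for that statement (no imputation), and n is reported
alongside.  SD is the sample standard deviation (n-1 denominator); with a
single rater it is undefined and reported as missing.  The cluster mean
is the unweighted arithmetic mean of its member statements' means — the
aggregation that reproduces published GCM cluster ratings — with a pooled
(rating-weighted) mode available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ClusterSolution
from .core_data import RatingScale, RatingTable


@dataclass(frozen=True)
class StatementStats:
    """Per-statement mean/SD/n for one (sub)group of raters."""

    table: pd.DataFrame  # columns statement_id, n, mean, sd (sd NaN if n == 1)
    subgroup: str
    n_raters: int
    scale: RatingScale

    def mean_of(self, statement_id: int) -> float:
        row = self.table[self.table["statement_id"] == statement_id]
        if row.empty:
            raise KeyError(statement_id)
        return float(row["mean"].iloc[0])

    @property
    def means(self) -> pd.Series:
        return self.table.set_index("statement_id")["mean"]


@dataclass(frozen=True)
class ClusterStats:
    """Per-cluster mean importance with membership."""

    table: pd.DataFrame  # cluster_id, cluster_label, n_statements, mean
    subgroup: str
    mode: str  # "mean_of_means" or "pooled"

    def mean_of(self, cluster: int | str) -> float:
        col = "cluster_label" if isinstance(cluster, str) else "cluster_id"
        row = self.table[self.table[col] == cluster]
        if row.empty:
            raise KeyError(cluster)
        return float(row["mean"].iloc[0])


def statement_stats(
    ratings: RatingTable,
    participant_ids: tuple[str, ...] | list[str] | None = None,
    subgroup: str = "all",
) -> StatementStats:
    """Available-case mean, sample SD, and n per statement.

    ``participant_ids`` restricts to a subgroup of raters; None keeps all.
    Raises if the restriction leaves no ratings (an empty subgroup would
    otherwise silently produce an empty table).
    """
    df = ratings.records
    if participant_ids is not None:
        df = df[df["participant_id"].isin(set(participant_ids))]
        if df.empty:
            raise ValueError(f"subgroup {subgroup!r} contains no ratings")
    grouped = df.groupby("statement_id")["rating"]
    out = pd.DataFrame(
        {
            "statement_id": grouped.mean().index,
            "n": grouped.count().to_numpy(),
            "mean": grouped.mean().to_numpy(),
            "sd": grouped.std(ddof=1).to_numpy(),  # NaN when n == 1
        }
    ).reset_index(drop=True)
    return StatementStats(
        table=out,
        subgroup=subgroup,
        n_raters=int(df["participant_id"].nunique()),
        scale=ratings.scale,
    )


def stats_from_precomputed(
    df: pd.DataFrame, subgroup: str = "all", scale: RatingScale | None = None
) -> StatementStats:
    """Wrap precomputed per-statement means (e.g. a published table) as stats.

    Expects columns ``statement_id`` and ``mean``; ``sd`` and ``n`` are
    carried through when present, else marked missing.  This is the input
    path for rating-only analyses where raw ratings were never deposited.
    """
    if not {"statement_id", "mean"}.issubset(df.columns):
        raise ValueError("precomputed stats need statement_id and mean columns")
    out = pd.DataFrame(
        {
            "statement_id": df["statement_id"].astype(int),
            "n": df["n"].astype(int) if "n" in df else pd.array([pd.NA] * len(df)),
            "mean": df["mean"].astype(float),
            "sd": df["sd"].astype(float) if "sd" in df else np.nan,
        }
    ).reset_index(drop=True)
    return StatementStats(
        table=out, subgroup=subgroup, n_raters=0, scale=scale or RatingScale()
    )


def cluster_means(
    stats: StatementStats,
    solution: ClusterSolution,
    mode: str = "mean_of_means",
) -> ClusterStats:
    """Cluster importance as the unweighted mean of member-statement means.

    ``pooled`` mode instead weights each statement mean by its n (equal to
    the overall rating mean when every statement has the same raters).
    """
    if mode not in ("mean_of_means", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    means = stats.means
    missing = [s for s in solution.assignment if s not in means.index]
    if missing:
        raise ValueError(f"statements without stats: {sorted(missing)}")
    rows = []
    for cid in solution.cluster_ids:
        members = solution.members(cid)
        m = means.loc[list(members)]
        if mode == "pooled":
            w = stats.table.set_index("statement_id")["n"].loc[list(members)]
            value = float(np.average(m, weights=w))
        else:
            value = float(m.mean())
        rows.append(
            {
                "cluster_id": cid,
                "cluster_label": solution.labels[cid],
                "n_statements": len(members),
                "mean": value,
            }
        )
    return ClusterStats(pd.DataFrame(rows), subgroup=stats.subgroup, mode=mode)


def rank_statements(stats: StatementStats, top_n: int | None = None) -> pd.DataFrame:
    """Statements by descending mean; ties broken by ascending statement id."""
    if top_n is not None and top_n > len(stats.table):
        raise ValueError(f"top_n={top_n} exceeds {len(stats.table)} statements")
    ranked = stats.table.sort_values(
        ["mean", "statement_id"], ascending=[False, True]
    ).reset_index(drop=True)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return ranked if top_n is None else ranked.head(top_n)


def count_clusters_above(cstats: ClusterStats, threshold: float) -> int:
    """Number of clusters with mean importance strictly above the threshold."""
    return int((cstats.table["mean"] > threshold).sum())


def write_statement_stats(stats: StatementStats, path) -> None:
    out = stats.table.copy()
    out.insert(1, "subgroup", stats.subgroup)
    out.to_csv(path, index=False, encoding="utf-8")


def write_cluster_stats(cstats: ClusterStats, path) -> None:
    out = cstats.table.copy()
    out.insert(2, "subgroup", cstats.subgroup)
    out["mean"] = out["mean"].round(2)  # reported precision; full kept in memory
    out.to_csv(path, index=False, encoding="utf-8")
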