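"""Subgroup comparisons: ladder graphs (pattern matching) and go-zones.

A ladder graph pairs the cluster mean importance ratings of two
participant subgroups and summarizes their agreement with a Pearson
correlation over the k paired cluster means.  A go-zone scatters the
per-statement means of two subgroups and splits the plane into four
quadrants at each group's grand mean (over statement means); quadrant HH
collects statements rated high by both groups — the actionable "go" zone.
A boundary value counts as high.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .clustering import ClusterSolution
from .core_data import ParticipantTable
from .ratings import StatementStats, cluster_means


@dataclass(frozen=True)
class LadderResult:
    """Paired cluster means for two subgroups with their correlation."""

    table: pd.DataFrame  # cluster_id, cluster_label, mean_a, mean_b
    r: float
    subgroup_a: str
    subgroup_b: str
    n_a: int
    n_b: int
    method: str = "pearson"


@dataclass(frozen=True)
class GoZoneResult:
    """Per-statement subgroup means with quadrant classification."""

    table: pd.DataFrame  # statement_id, mean_a, mean_b, quadrant
    threshold_a: float
    threshold_b: float
    subgroup_a: str
    subgroup_b: str

    @property
    def quadrant_counts(self) -> dict[str, int]:
        counts = {"HH": 0, "HL": 0, "LH": 0, "LL": 0}
        counts.update(self.table["quadrant"].value_counts().to_dict())
        return counts


def _correlation(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "spearman":
        a = pd.Series(a).rank().to_numpy()
        b = pd.Series(b).rank().to_numpy()
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sa, sb = a.std(ddof=0), b.std(ddof=0)
    if sa == 0 or sb == 0:
        raise ValueError("correlation undefined: a subgroup's means are constant")
    return float(np.cov(a, b, ddof=0)[0, 1] / (sa * sb))


def pattern_match(
    stats_a: StatementStats,
    stats_b: StatementStats,
    solution: ClusterSolution,
    method: str = "pearson",
) -> LadderResult:
    """Ladder comparison of two subgroups' cluster mean ratings."""
    if solution.k < 2:
        raise ValueError("pattern matching needs at least 2 clusters")
    ca = cluster_means(stats_a, solution).table
    cb = cluster_means(stats_b, solution).table
    merged = ca.merge(
        cb[["cluster_id", "mean"]], on="cluster_id", suffixes=("_a", "_b")
    ).rename(columns={"mean_a": "mean_a", "mean_b": "mean_b"})
    r = _correlation(
        merged["mean_a"].to_numpy(), merged["mean_b"].to_numpy(), method
    )
    return LadderResult(
        table=merged[["cluster_id", "cluster_label", "mean_a", "mean_b"]],
        r=r,
        subgroup_a=stats_a.subgroup,
        subgroup_b=stats_b.subgroup,
        n_a=stats_a.n_raters,
        n_b=stats_b.n_raters,
        method=method,
    )


def go_zone(
    stats_a: StatementStats,
    stats_b: StatementStats,
    statement_ids: Iterable[int] | None = None,
) -> GoZoneResult:
    """Quadrant classification of statement means for two subgroups.

    ``statement_ids`` optionally restricts to a subset (e.g. one
    cluster's statements); thresholds are the grand means over the
    statements actually displayed.
    """
    ma, mb = stats_a.means, stats_b.means
    common = ma.index.intersection(mb.index)
    if statement_ids is not None:
        subset = [s for s in statement_ids if s in common]
        if not subset:
            raise ValueError("empty statement subset for go-zone")
        common = pd.Index(sorted(subset))
    if common.empty:
        raise ValueError("no statements rated by both subgroups")
    a = ma.loc[common].to_numpy()
    b = mb.loc[common].to_numpy()
    ta, tb = float(a.mean()), float(b.mean())
    high_a, high_b = a >= ta, b >= tb
    quadrant = np.where(
        high_a, np.where(high_b, "HH", "HL"), np.where(high_b, "LH", "LL")
    )
    table = pd.DataFrame(
        {
            "statement_id": common.to_numpy(),
            "mean_a": a,
            "mean_b": b,
            "quadrant": quadrant,
        }
    )
    return GoZoneResult(
        table=table,
        threshold_a=ta,
        threshold_b=tb,
        subgroup_a=stats_a.subgroup,
        subgroup_b=stats_b.subgroup,
    )


# ---------------------------------------------------------------------------
# Subgroup presets mirroring the study's comparisons
# ---------------------------------------------------------------------------

Predicate = Callable[[pd.Series], bool]

SUBGROUP_PRESETS: dict[str, Predicate] = {
    "symptoms_none": lambda row: row.get("symptom_severity") == "none",
    "symptoms_mild": lambda row: row.get("symptom_severity") == "mild",
    "symptoms_moderate": lambda row: row.get("symptom_severity") == "moderate",
    "treated": lambda row: row.get("treatment_experience") not in ("none", "", None),
    "untreated": lambda row: row.get("treatment_experience") == "none",
    "psychotherapy_only": lambda row: row.get("treatment_experience")
    == "psychotherapy_only",
    "medication_any": lambda row: row.get("treatment_experience")
    in ("medication_only", "combination"),
}


def resolve_subgroup(
    participants: ParticipantTable, expr: str
) -> tuple[str, tuple[str, ...]]:
    """Resolve a preset name or ``attribute=value`` expression to ids."""
    if expr in SUBGROUP_PRESETS:
        return expr, participants.select(SUBGROUP_PRESETS[expr])
    if "=" in expr:
        attr, value = expr.split("=", 1)
        return expr, participants.select(lambda row: row.get(attr) == value)
    raise KeyError(
        f"unknown subgroup {expr!r}; use a preset "
        f"({', '.join(sorted(SUBGROUP_PRESETS))}) or attribute=value"
    )


def write_ladder(result: LadderResult, path) -> None:
    result.table.to_csv(path, index=False, encoding="utf-8")


def write_go_zone(result: GoZoneResult, path) -> None:
    result.table.to_csv(path, index=False, encoding="utf-8")
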