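"""End-to-end pipeline driver: configuration, staging, artifacts, manifest.

Two entry modes.  ``full`` runs the whole chain on raw study files:
validate sorts -> similarity -> cut-off -> dissimilarity -> MDS point map
-> Ward tree -> k-cluster solution (plus optional expert moves) ->
bridging -> rating statistics -> subgroup comparisons.  ``rating-only``
starts from precomputed per-statement means plus a cluster assignment
(the situation when raw sort/rating records are unavailable but the
published statement table is) and produces the cluster and ranking
outputs only.

Every run writes its artifacts plus ``manifest.json`` — a config echo,
package version, seed, headline numbers, and a SHA-256 checksum per
artifact — sufficient to re-run bit-identically via
:func:`run_from_manifest`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import (
    ClusterSolution,
    apply_moves,
    bridging_values,
    cut_to_solution,
    read_moves,
    ward_tree,
    write_clusters,
    write_tree,
)
from .core_data import (
    RatingScale,
    read_participants,
    read_ratings,
    read_sorts,
    read_statements,
    validate_sorts,
)
from .point_map import fit_point_map, point_map_manifest, write_point_map
from .ratings import (
    cluster_means,
    count_clusters_above,
    rank_statements,
    statement_stats,
    stats_from_precomputed,
    write_cluster_stats,
    write_statement_stats,
)
from .similarity import (
    apply_cutoff,
    group_similarity,
    similarity_manifest,
    to_dissimilarity,
    write_matrix,
)
from .subgroup_compare import (
    go_zone,
    pattern_match,
    resolve_subgroup,
    write_go_zone,
    write_ladder,
)

logger = logging.getLogger("gcmkit")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a run needs; every field maps 1:1 to a YAML key."""

    mode: str = "full"  # "full" or "rating-only"
    out_dir: str = "gcm_out"
    # full-mode inputs
    statements: str | None = None
    sorts: str | None = None
    ratings: str | None = None
    participants: str | None = None
    # rating-only input: statement table with cluster_id/cluster_label/mean
    stats: str | None = None
    moves: str | None = None
    # analysis settings
    scale_min: int = 1
    scale_max: int = 4
    cutoff: int = 1
    dims: int = 2
    n_restarts: int = 10
    max_iter: int = 300
    tol: float = 1e-6
    seed: int = 0
    k: int = 10
    k_range: tuple[int, int] | None = None  # candidate solutions for review
    top_n: int = 10
    rating_threshold: float = 3.0
    subgroup_a: str | None = None
    subgroup_b: str | None = None
    make_figures: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in raw and raw["k_range"] is not None:
            raw = dict(raw, k_range=tuple(raw["k_range"]))
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["k_range"] is not None:
            d["k_range"] = list(d["k_range"])
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stress: float | None
    n_sorters_accepted: int | None
    n_sorters_rejected: int | None
    n_sorters_incomplete: int | None
    similarity: dict | None
    point_map: dict | None
    headline: dict
    checksums: dict[str, str]
    timestamp: str

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, exc) from exc

        return wrapped

    return deco


def _solution_from_table(df: pd.DataFrame) -> ClusterSolution:
    need = {"statement_id", "cluster_id"}
    if not need.issubset(df.columns):
        raise ValueError(f"cluster table needs columns {sorted(need)}")
    assignment = dict(
        zip(df["statement_id"].astype(int), df["cluster_id"].astype(int))
    )
    if "cluster_label" in df.columns:
        labels = {
            int(c): str(l)
            for c, l in df[["cluster_id", "cluster_label"]]
            .drop_duplicates()
            .itertuples(index=False)
        }
    else:
        labels = {c: f"Cluster {c}" for c in sorted(set(assignment.values()))}
    return ClusterSolution(
        k=len(labels),
        assignment=assignment,
        labels=labels,
        provenance=("loaded from cluster table",),
    )


def run_pipeline(config: RunConfig) -> RunManifest:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.mode == "rating-only":
        return _run_rating_only(config, out)
    if config.mode != "full":
        raise ValueError(f"unknown mode {config.mode!r}")
    return _run_full(config, out)


def _run_rating_only(config: RunConfig, out: Path) -> RunManifest:
    if not config.stats:
        raise StageError("inputs", FileNotFoundError("rating-only mode needs 'stats'"))
    scale = RatingScale(config.scale_min, config.scale_max, labels=())

    @_stage("load-stats")
    def load():
        df = pd.read_csv(config.stats, encoding="utf-8")
        return stats_from_precomputed(df, scale=scale), _solution_from_table(df)

    stats, solution = load()
    if config.moves:
        solution = apply_moves(solution, read_moves(config.moves))

    cstats = cluster_means(stats, solution)
    ranked = rank_statements(stats, top_n=config.top_n)
    n_above = count_clusters_above(cstats, config.rating_threshold)

    write_statement_stats(stats, out / "statement_stats.csv")
    write_cluster_stats(cstats, out / "cluster_stats.csv")
    ranked.round(6).to_csv(out / "top_statements.csv", index=False, encoding="utf-8")
    _write_report(
        out / "report.md", cstats=cstats, ranked=ranked, n_above=n_above,
        threshold=config.rating_threshold, stress=None, ladder=None,
    )
    artifacts = ["statement_stats.csv", "cluster_stats.csv", "top_statements.csv", "report.md"]
    headline = {
        "n_statements": int(len(stats.table)),
        "n_clusters": solution.k,
        "clusters_above_threshold": n_above,
        "top_statement_id": int(ranked.iloc[0]["statement_id"]),
        "top_statement_mean": float(ranked.iloc[0]["mean"]),
    }
    return _finish(config, out, artifacts, headline=headline)


def _run_full(config: RunConfig, out: Path) -> RunManifest:
    scale = RatingScale(config.scale_min, config.scale_max, labels=())

    @_stage("read-inputs")
    def read_inputs():
        if not config.statements or not Path(config.statements).exists():
            raise FileNotFoundError(f"statements file: {config.statements}")
        stmts = read_statements(config.statements)
        if not config.sorts or not Path(config.sorts).exists():
            raise FileNotFoundError(f"sorts file: {config.sorts}")
        sorts = read_sorts(config.sorts, stmts)
        ratings = (
            read_ratings(config.ratings, stmts, scale) if config.ratings else None
        )
        parts = read_participants(config.participants) if config.participants else None
        return stmts, sorts, ratings, parts

    statements, sorts, ratings, participants = read_inputs()

    report = _stage("validate")(validate_sorts)(sorts, statements)
    (out / "validation.json").write_text(
        json.dumps(
            {"status": dict(report.status), "reasons": {k: list(v) for k, v in report.reasons.items()},
             "counts": report.counts},
            indent=2,
        )
    )
    if not report.accepted_records:
        raise StageError("validate", ValueError("no accepted sort records"))

    T_raw = _stage("similarity")(group_similarity)(report.accepted_records, statements)
    T = _stage("cutoff")(apply_cutoff)(T_raw, config.cutoff)
    D = _stage("dissimilarity")(to_dissimilarity)(T)
    write_matrix(T_raw, out / "similarity_raw.csv")
    write_matrix(T, out / "similarity.csv")
    write_matrix(D, out / "dissimilarity.csv")

    pm = _stage("point-map")(fit_point_map)(
        D, dims=config.dims, seed=config.seed, n_restarts=config.n_restarts,
        max_iter=config.max_iter, tol=config.tol,
    )
    write_point_map(pm, out / "point_map.csv")

    tree = _stage("cluster")(ward_tree)(pm)
    write_tree(tree, out / "tree.json")
    solution = cut_to_solution(tree, config.k)
    if config.moves:
        solution = _stage("moves")(apply_moves)(solution, read_moves(config.moves))
    bridging = _stage("bridging")(bridging_values)(pm, T, solution)
    if bridging.isolated:
        logger.warning(
            "statements with no surviving co-sorts (bridging falls back to "
            "mean map distance): %s", list(bridging.isolated),
        )
    write_clusters(solution, out / "clusters.csv", bridging)
    artifacts = [
        "validation.json", "similarity_raw.csv", "similarity.csv",
        "dissimilarity.csv", "point_map.csv", "tree.json", "clusters.csv",
    ]
    if config.k_range:
        lo, hi = config.k_range
        rows = {sid: {"statement_id": sid} for sid in sorted(statements.ids)}
        for k in range(lo, min(hi, len(statements)) + 1):
            sol_k = cut_to_solution(tree, k)
            for sid, cid in sol_k.assignment.items():
                rows[sid][f"k{k}"] = cid
        pd.DataFrame(list(rows.values())).to_csv(
            out / "candidate_solutions.csv", index=False, encoding="utf-8"
        )
        artifacts.append("candidate_solutions.csv")

    stats = cstats = ranked = ladder = gz = None
    n_above = None
    if ratings is not None:
        stats = _stage("ratings")(statement_stats)(ratings)
        cstats = cluster_means(stats, solution)
        ranked = rank_statements(stats, top_n=min(config.top_n, len(stats.table)))
        n_above = count_clusters_above(cstats, config.rating_threshold)
        write_statement_stats(stats, out / "statement_stats.csv")
        write_cluster_stats(cstats, out / "cluster_stats.csv")
        ranked.round(6).to_csv(out / "top_statements.csv", index=False, encoding="utf-8")
        artifacts += ["statement_stats.csv", "cluster_stats.csv", "top_statements.csv"]

    if ratings is not None and participants is not None and config.subgroup_a and config.subgroup_b:
        @_stage("subgroups")
        def compare():
            name_a, ids_a = resolve_subgroup(participants, config.subgroup_a)
            name_b, ids_b = resolve_subgroup(participants, config.subgroup_b)
            sa = statement_stats(ratings, ids_a, subgroup=name_a)
            sb = statement_stats(ratings, ids_b, subgroup=name_b)
            return pattern_match(sa, sb, solution), go_zone(sa, sb)

        ladder, gz = compare()
        write_ladder(ladder, out / "ladder.csv")
        write_go_zone(gz, out / "gozone.csv")
        artifacts += ["ladder.csv", "gozone.csv"]

    _write_report(
        out / "report.md", cstats=cstats, ranked=ranked, n_above=n_above,
        threshold=config.rating_threshold, stress=pm.stress, ladder=ladder,
    )
    artifacts.append("report.md")

    if config.make_figures:
        figs = _stage("figures")(make_figures)(out, pm, solution, ladder, gz)
        artifacts += figs

    headline = {
        "n_statements": len(statements),
        "n_sorters_total": report.n_total,
        "stress": pm.stress,
        "n_clusters": solution.k,
        "n_isolated_statements": len(bridging.isolated),
    }
    if cstats is not None:
        headline["clusters_above_threshold"] = n_above
    if ladder is not None:
        headline["ladder_r"] = ladder.r
    return _finish(
        config, out, artifacts, headline=headline, report=report,
        similarity=similarity_manifest(T), pm_info=point_map_manifest(pm),
    )


def _finish(config, out, artifacts, headline, report=None, similarity=None, pm_info=None):
    checksums = {name: _sha256(out / name) for name in sorted(artifacts)}
    counts = report.counts if report is not None else None
    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        seed=config.seed,
        stress=None if pm_info is None else pm_info["stress"],
        n_sorters_accepted=None if counts is None else counts["accepted"],
        n_sorters_rejected=None if counts is None else counts["rejected"],
        n_sorters_incomplete=None if counts is None else counts["incomplete"],
        similarity=similarity,
        point_map=pm_info,
        headline=headline,
        checksums=checksums,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(out / "manifest.json")
    return manifest


def run_from_manifest(manifest_path: str | Path) -> RunManifest:
    """Re-run a pipeline from its manifest's config echo."""
    payload = json.loads(Path(manifest_path).read_text())
    return run_pipeline(RunConfig.from_dict(payload["config"]))


def _write_report(path, cstats, ranked, n_above, threshold, stress, ladder) -> None:
    lines = ["# Concept mapping run summary", ""]
    if stress is not None:
        lines += [f"Point map stress-1: {stress:.4f}", ""]
    if cstats is not None:
        lines += ["## Cluster importance (mean of member-statement means)", ""]
        lines.append("| cluster | label | n statements | mean |")
        lines.append("|---|---|---|---|")
        for row in cstats.table.itertuples():
            lines.append(
                f"| {row.cluster_id} | {row.cluster_label} | {row.n_statements} "
                f"| {row.mean:.2f} |"
            )
        lines += ["", f"Clusters with mean above {threshold:g}: {n_above}", ""]
    if ranked is not None:
        lines += ["## Highest-rated statements", ""]
        lines.append("| rank | statement | mean |")
        lines.append("|---|---|---|")
        for row in ranked.itertuples():
            lines.append(f"| {row.rank} | {row.statement_id} | {row.mean:.2f} |")
        lines.append("")
    if ladder is not None:
        lines += [
            "## Subgroup pattern match",
            "",
            f"{ladder.subgroup_a} (n={ladder.n_a}) vs {ladder.subgroup_b} "
            f"(n={ladder.n_b}): r = {ladder.r:.2f}",
            "",
        ]
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# Figures (static exports; Agg backend so no display is needed)
# ---------------------------------------------------------------------------


def make_figures(out: Path, pm, solution, ladder=None, gz=None) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.spatial import ConvexHull

    written = []
    fig, ax = plt.subplots(figsize=(7, 6))
    coords = pm.coordinates
    idx = {sid: i for i, sid in enumerate(pm.ids)}
    cmap = plt.get_cmap("tab10")
    for j, cid in enumerate(solution.cluster_ids):
        pts = coords[[idx[s] for s in solution.members(cid)]]
        color = cmap(j % 10)
        ax.scatter(pts[:, 0], pts[:, 1], s=18, color=color, label=solution.labels[cid])
        if len(pts) >= 3:
            hull = ConvexHull(pts)
            poly = pts[list(hull.vertices) + [hull.vertices[0]]]
            ax.fill(poly[:, 0], poly[:, 1], alpha=0.15, color=color)
    ax.set_title(f"Point map (stress-1 = {pm.stress:.3f})")
    ax.legend(fontsize=7, loc="best")
    fig.savefig(out / "map.png", dpi=120)
    plt.close(fig)
    written.append("map.png")

    if ladder is not None:
        fig, ax = plt.subplots(figsize=(5, 6))
        for row in ladder.table.itertuples():
            ax.plot([0, 1], [row.mean_a, row.mean_b], marker="o", lw=1)
            ax.annotate(str(row.cluster_id), (0, row.mean_a), fontsize=7,
                        ha="right", xytext=(-4, 0), textcoords="offset points")
        ax.set_xticks([0, 1])
        ax.set_xticklabels([ladder.subgroup_a, ladder.subgroup_b])
        ax.set_ylabel("cluster mean importance")
        ax.set_title(f"Ladder graph (r = {ladder.r:.2f})")
        fig.savefig(out / "ladder.png", dpi=120)
        plt.close(fig)
        written.append("ladder.png")

    if gz is not None:
        fig, ax = plt.subplots(figsize=(6, 6))
        ax.scatter(gz.table["mean_a"], gz.table["mean_b"], s=14)
        ax.axvline(gz.threshold_a, color="grey", lw=0.8)
        ax.axhline(gz.threshold_b, color="grey", lw=0.8)
        ax.set_xlabel(f"mean ({gz.subgroup_a})")
        ax.set_ylabel(f"mean ({gz.subgroup_b})")
        ax.set_title("Go-zone")
        fig.savefig(out / "gozone.png", dpi=120)
        plt.close(fig)
        written.append("gozone.png")
    return written
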