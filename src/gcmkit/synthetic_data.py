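"""Synthetic GCM studies with planted structure.

Emulates the data a sorting-and-rating exercise produces: S statements in
K latent thematic clusters; sorters who start from the latent partition
and corrupt it (pile splits for "splitters", pile merges for "lumpers",
and independent per-statement mislabels at rate epsilon); raters who emit
ordinal importance ratings as round(importance + rater bias + noise)
clamped to the scale; and a participant roster with symptom-severity and
treatment-experience attributes drawn with proportions like those of the
study population.  Optional subgroup shifts move a subgroup's latent
importances up or down to plant rating differences between groups.

Defaults (S=40, K=5, 30 sorters, 30 raters, epsilon=0.05, split/merge
channels off) describe a moderately noisy study of the size at which
concept maps are reported to stabilize, scaled down from 79 statements
for fast simulation; cluster importance effects sit in the upper half of
the 1-4 scale so that rating distributions are left-skewed, as observed
in real importance data.  The split/merge channels model systematic
lumpers and splitters and are opted into per study; they interact with
the mislabel channel to produce bridging statements that a 2-D map
genuinely cannot place (see the methods note).

All randomness flows from a single seed: per-participant substreams are
derived with stable spawn keys (role, index), so adding raters never
perturbs the sorters' draws and vice versa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterSolution
from .core_data import (
    ParticipantTable,
    RatingScale,
    RatingTable,
    SortRecord,
    StatementSet,
    write_participants,
    write_ratings,
    write_sorts,
    write_statements,
)

# attribute vocabularies and sampling weights mirroring the study roster
SEVERITY_LEVELS = ("none", "mild", "moderate", "severe")
SEVERITY_WEIGHTS = (0.37, 0.28, 0.35, 0.0)
TREATMENT_LEVELS = ("none", "psychotherapy_only", "medication_only", "combination")
TREATMENT_WEIGHTS = (0.22, 0.09, 0.06, 0.63)

_ROLE_STRUCTURE, _ROLE_SORTER, _ROLE_RATER, _ROLE_ROSTER = range(4)


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; see module docstring for the model."""

    S: int = 40
    K: int = 5
    n_sorters: int = 30
    n_raters: int = 30
    epsilon: float = 0.05  # per-statement mislabel probability
    p_split: float = 0.0  # per-sorter pile-split probability (off by default)
    p_merge: float = 0.0  # per-sorter pile-merge probability (off by default)
    cluster_effects: tuple[float, ...] | None = None  # K latent importances
    rater_bias_sd: float = 0.3
    noise_sd: float = 0.5
    subgroup_shifts: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    scale: RatingScale = field(default_factory=RatingScale)
    seed: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.K <= self.S:
            raise ValueError(f"need S >= K >= 1, got S={self.S}, K={self.K}")
        if self.n_sorters < 1 or self.n_raters < 0:
            raise ValueError("need at least one sorter and nonnegative raters")
        for name in ("epsilon", "p_split", "p_merge"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.rater_bias_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.cluster_effects is not None and len(self.cluster_effects) != self.K:
            raise ValueError("cluster_effects must have K entries")

    def effects(self) -> np.ndarray:
        if self.cluster_effects is not None:
            return np.asarray(self.cluster_effects, dtype=float)
        lo = self.scale.min_code + 0.5 * (self.scale.max_code - self.scale.min_code)
        hi = self.scale.max_code - 0.1 * (self.scale.max_code - self.scale.min_code)
        return np.linspace(lo, hi, self.K)


@dataclass(frozen=True)
class SyntheticStudy:
    """Complete generated study bundle with its ground truth."""

    statements: StatementSet
    planted: ClusterSolution
    sorts: tuple[SortRecord, ...]
    ratings: RatingTable
    participants: ParticipantTable
    true_importances: Mapping[int, float]
    config: SyntheticConfig


def _substream(seed: int, role: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(role, index))
    )


def planted_partition(S: int, K: int) -> dict[int, int]:
    """Contiguous balanced blocks: statement i -> cluster 1 + (i-1)*K // S."""
    return {i: 1 + ((i - 1) * K) // S for i in range(1, S + 1)}


def simulate_sorter(
    planted: Mapping[int, int],
    epsilon: float,
    p_split: float,
    p_merge: float,
    rng: np.random.Generator,
    participant_id: str = "sorter",
) -> SortRecord:
    """One sorter's noisy copy of the planted partition.

    In order: with probability p_split a random pile of size >= 2 is split
    in two; with probability p_merge two random piles are merged; then
    each statement independently moves to a uniformly chosen *other* pile
    with probability epsilon.
    """
    piles: list[set[int]] = []
    for cid in sorted(set(planted.values())):
        piles.append({s for s, c in planted.items() if c == cid})

    if rng.random() < p_split:
        splittable = [p for p in piles if len(p) >= 2]
        if splittable:
            pile = splittable[int(rng.integers(len(splittable)))]
            members = sorted(pile)
            rng.shuffle(members)
            cut = int(rng.integers(1, len(members)))
            piles.remove(pile)
            piles.extend([set(members[:cut]), set(members[cut:])])
    if rng.random() < p_merge and len(piles) >= 2:
        i, j = rng.choice(len(piles), size=2, replace=False)
        merged = piles[i] | piles[j]
        piles = [p for k, p in enumerate(piles) if k not in (i, j)]
        piles.append(merged)

    if len(piles) > 1 and epsilon > 0:
        for s in sorted(planted):
            if rng.random() < epsilon:
                src = next(k for k, p in enumerate(piles) if s in p)
                others = [k for k in range(len(piles)) if k != src]
                dst = others[int(rng.integers(len(others)))]
                piles[src].discard(s)
                piles[dst].add(s)
    piles = [p for p in piles if p]
    return SortRecord(
        participant_id,
        tuple((f"pile_{k + 1}", frozenset(p)) for k, p in enumerate(piles)),
    )


def simulate_rater(
    true_importances: Mapping[int, float],
    rater_bias_sd: float,
    noise_sd: float,
    scale: RatingScale,
    rng: np.random.Generator,
    shift: float = 0.0,
) -> dict[int, int]:
    """Ordinal ratings: round(importance + shift + bias + noise), clamped."""
    bias = rng.normal(0.0, rater_bias_sd) if rater_bias_sd > 0 else 0.0
    out: dict[int, int] = {}
    for sid in sorted(true_importances):
        latent = true_importances[sid] + shift + bias
        if noise_sd > 0:
            latent += rng.normal(0.0, noise_sd)
        code = int(np.rint(latent))
        out[sid] = int(np.clip(code, scale.min_code, scale.max_code))
    return out


def simulate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a full study bundle, deterministic given ``config.seed``."""
    S, K = config.S, config.K
    statements = StatementSet(
        tuple((i, f"statement {i:03d} (theme {1 + ((i - 1) * K) // S})") for i in range(1, S + 1))
    )
    planted_map = planted_partition(S, K)
    planted = ClusterSolution(
        k=K,
        assignment=planted_map,
        labels={c: f"Theme {c}" for c in range(1, K + 1)},
        provenance=("planted partition",),
    )
    effects = config.effects()
    true_importances = {i: float(effects[planted_map[i] - 1]) for i in planted_map}

    n_participants = max(config.n_sorters, config.n_raters)
    roster_rng = _substream(config.seed, _ROLE_ROSTER)
    pids = [f"p{i + 1:03d}" for i in range(n_participants)]
    severity = roster_rng.choice(
        SEVERITY_LEVELS, size=n_participants, p=np.asarray(SEVERITY_WEIGHTS) / sum(SEVERITY_WEIGHTS)
    )
    treatment = roster_rng.choice(
        TREATMENT_LEVELS, size=n_participants, p=np.asarray(TREATMENT_WEIGHTS) / sum(TREATMENT_WEIGHTS)
    )
    participants = ParticipantTable(
        pd.DataFrame(
            {
                "participant_id": pids,
                "symptom_severity": severity,
                "treatment_experience": treatment,
            }
        )
    )

    sorts = tuple(
        simulate_sorter(
            planted_map,
            config.epsilon,
            config.p_split,
            config.p_merge,
            _substream(config.seed, _ROLE_SORTER, i),
            participant_id=pids[i],
        )
        for i in range(config.n_sorters)
    )

    attr_rows = participants.table.set_index("participant_id")
    records = []
    for i in range(config.n_raters):
        pid = pids[i]
        shift = 0.0
        for attr, table in config.subgroup_shifts.items():
            shift += table.get(str(attr_rows.loc[pid].get(attr)), 0.0)
        ratings_i = simulate_rater(
            true_importances,
            config.rater_bias_sd,
            config.noise_sd,
            config.scale,
            _substream(config.seed, _ROLE_RATER, i),
            shift=shift,
        )
        records.extend(
            {"participant_id": pid, "statement_id": sid, "rating": r}
            for sid, r in ratings_i.items()
        )
    ratings = RatingTable(
        pd.DataFrame(records, columns=["participant_id", "statement_id", "rating"]),
        config.scale,
    )
    return SyntheticStudy(
        statements=statements,
        planted=planted,
        sorts=sorts,
        ratings=ratings,
        participants=participants,
        true_importances=true_importances,
        config=config,
    )


def recovery_ari(
    planted: ClusterSolution | Mapping[int, int],
    recovered: ClusterSolution | Mapping[int, int],
) -> float:
    """Adjusted Rand index between two partitions of the same statements.

    Computed from the contingency table:
    ARI = (sum_ij C(n_ij,2) - E) / (max - E) with
    E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2) and
    max = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2.
    """
    pa = planted.assignment if isinstance(planted, ClusterSolution) else planted
    pb = recovered.assignment if isinstance(recovered, ClusterSolution) else recovered
    if set(pa) != set(pb):
        raise ValueError("partitions cover different statement sets")
    sids = sorted(pa)
    la = pd.Categorical([pa[s] for s in sids]).codes
    lb = pd.Categorical([pb[s] for s in sids]).codes
    n = len(sids)
    contingency = np.zeros((la.max() + 1, lb.max() + 1), dtype=np.int64)
    for x, y in zip(la, lb):
        contingency[x, y] += 1

    def comb2(v: np.ndarray) -> float:
        return float((v * (v - 1) // 2).sum())

    index = comb2(contingency.ravel())
    sum_a = comb2(contingency.sum(axis=1))
    sum_b = comb2(contingency.sum(axis=0))
    total = n * (n - 1) / 2
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:  # both partitions trivial (all-one or all-singleton)
        return 1.0 if index == expected else 0.0
    return float((index - expected) / (max_index - expected))


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write the four study CSVs plus truth.json (ground truth + config)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_statements(study.statements, outdir / "statements.csv")
    write_sorts(study.sorts, outdir / "sorts.csv")
    write_ratings(study.ratings, outdir / "ratings.csv")
    write_participants(study.participants, outdir / "participants.csv")
    cfg = asdict(study.config)
    cfg["scale"] = {
        "min_code": study.config.scale.min_code,
        "max_code": study.config.scale.max_code,
    }
    truth = {
        "planted_partition": {str(s): c for s, c in sorted(study.planted.assignment.items())},
        "true_importances": {str(s): v for s, v in sorted(study.true_importances.items())},
        "config": cfg,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
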