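"""Domain types and strict tabular I/O for group concept mapping studies.

A GCM study produces four flat files: the statement list, long-format card
sorts (participant, pile, statement), long-format importance ratings, and a
participant attribute table.  This module defines the in-memory containers
for each, the CSV readers/writers with schema validation, and the rule-based
screening of sort records (sorters who lump everything into one pile or
split everything into singletons did not follow the sorting instructions
and are excluded from the similarity analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("gcmkit")

# Importance categories of the study's four-point Likert question, coded 1-4
# internally so that category means land on the familiar 1-4 scale.
DEFAULT_SCALE_LABELS = (
    "relatively unimportant",
    "a little important",
    "moderately important",
    "very important",
)


class SchemaError(ValueError):
    """A tabular input violates its declared schema."""


class ReferentialError(ValueError):
    """A row refers to an entity (statement, cluster) that does not exist."""


class DuplicatePlacementError(ValueError):
    """A participant placed the same statement in more than one pile."""


class RangeError(ValueError):
    """A rating code falls outside the configured ordinal scale."""


class VocabularyError(ValueError):
    """An attribute value is not in the declared vocabulary."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StatementSet:
    """Ordered list of (statement_id, text) pairs with unique positive ids."""

    entries: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate statement ids: {dupes}")
        if any(i <= 0 for i in ids):
            raise SchemaError("statement ids must be strictly positive")
        if any(not text for _, text in self.entries):
            raise SchemaError("statement text must be non-empty")

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(sid for sid, _ in self.entries)

    @property
    def texts(self) -> dict[int, str]:
        return dict(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, statement_id: int) -> bool:
        return statement_id in set(self.ids)


@dataclass(frozen=True)
class SortRecord:
    """One participant's partition of statements into labelled piles.

    Piles must be disjoint; completeness (union covers the full statement
    set) is a property of the record relative to a :class:`StatementSet`
    and is checked by :func:`validate_sorts`.
    """

    participant_id: str
    piles: tuple[tuple[str, frozenset[int]], ...]

    def __post_init__(self) -> None:
        if not self.piles:
            raise SchemaError(f"sorter {self.participant_id!r} has no piles")
        seen: set[int] = set()
        for _, members in self.piles:
            overlap = seen & members
            if overlap:
                raise DuplicatePlacementError(
                    f"sorter {self.participant_id!r} placed statements "
                    f"{sorted(overlap)} in more than one pile"
                )
            seen |= members

    @property
    def sorted_ids(self) -> frozenset[int]:
        out: set[int] = set()
        for _, members in self.piles:
            out |= members
        return frozenset(out)

    def is_complete(self, statements: StatementSet) -> bool:
        return self.sorted_ids == frozenset(statements.ids)

    def pile_of(self, statement_id: int) -> str:
        for label, members in self.piles:
            if statement_id in members:
                return label
        raise KeyError(statement_id)


@dataclass(frozen=True)
class RatingScale:
    """Ordinal rating scale: integer codes min_code..max_code with labels."""

    min_code: int = 1
    max_code: int = 4
    labels: tuple[str, ...] = DEFAULT_SCALE_LABELS

    def __post_init__(self) -> None:
        if self.max_code <= self.min_code:
            raise SchemaError("max_code must exceed min_code")
        n = self.max_code - self.min_code + 1
        if self.labels and len(self.labels) != n:
            raise SchemaError(f"expected {n} category labels, got {len(self.labels)}")

    def __contains__(self, code: int) -> bool:
        return self.min_code <= code <= self.max_code


@dataclass(frozen=True)
class RatingTable:
    """Long-format ratings: one row per (participant, statement)."""

    records: pd.DataFrame  # columns participant_id, statement_id, rating
    scale: RatingScale

    def __post_init__(self) -> None:
        df = self.records
        expected = ["participant_id", "statement_id", "rating"]
        if list(df.columns) != expected:
            raise SchemaError(f"rating columns must be {expected}")
        bad = df[~df["rating"].isin(range(self.scale.min_code, self.scale.max_code + 1))]
        if not bad.empty:
            row = bad.iloc[0]
            raise RangeError(
                f"rating {row['rating']} for participant {row['participant_id']!r}, "
                f"statement {row['statement_id']} outside scale "
                f"[{self.scale.min_code}, {self.scale.max_code}]"
            )
        if df.duplicated(["participant_id", "statement_id"]).any():
            raise SchemaError("duplicate (participant, statement) rating")

    @property
    def participants(self) -> tuple[str, ...]:
        return tuple(self.records["participant_id"].unique())

    def for_participants(self, keep: Iterable[str]) -> "RatingTable":
        keep = set(keep)
        sub = self.records[self.records["participant_id"].isin(keep)].reset_index(drop=True)
        return RatingTable(sub, self.scale)


@dataclass(frozen=True)
class ParticipantTable:
    """Participant attributes keyed by unique participant_id."""

    table: pd.DataFrame  # first column participant_id, rest attributes

    def __post_init__(self) -> None:
        df = self.table
        if df.columns[0] != "participant_id":
            raise SchemaError("first column must be participant_id")
        if df["participant_id"].duplicated().any():
            dupes = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
            raise SchemaError(f"duplicate participant ids: {dupes}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.table["participant_id"])

    def select(self, predicate: Callable[[pd.Series], bool]) -> tuple[str, ...]:
        """Participant ids whose attribute row satisfies the predicate."""
        mask = self.table.apply(predicate, axis=1)
        return tuple(self.table.loc[mask, "participant_id"])


# Validation outcome per sorter.
ACCEPTED = "accepted"
REJECTED = "rejected"
INCOMPLETE = "incomplete"

# Reason codes for non-accepted sorts.
ALL_ONE_PILE = "ALL_ONE_PILE"
ALL_SINGLETONS = "ALL_SINGLETONS"
INCOMPLETE_CODE = "INCOMPLETE"
DUPLICATE = "DUPLICATE"


@dataclass(frozen=True)
class SortPolicy:
    """Operationalisation of the sorting rules used to screen sorters.

    ``one_pile`` rejects sorters who put every statement in a single pile
    (sorting by nothing); ``singleton_fraction``/``singleton_pile_ratio``
    reject near-total singleton sorts (no grouping at all): a sort is
    rejected when at least ``singleton_fraction`` of its piles are
    singletons AND the pile count is at least ``singleton_pile_ratio``
    times the statement count.
    """

    one_pile: bool = True
    singleton_fraction: float = 0.9
    singleton_pile_ratio: float = 0.9


@dataclass(frozen=True)
class ValidationReport:
    """Per-sorter classification with reason codes and summary counts."""

    status: Mapping[str, str]  # participant_id -> accepted/rejected/incomplete
    reasons: Mapping[str, tuple[str, ...]]
    accepted_records: tuple[SortRecord, ...] = field(repr=False, default=())

    @property
    def counts(self) -> dict[str, int]:
        out = {ACCEPTED: 0, REJECTED: 0, INCOMPLETE: 0}
        for s in self.status.values():
            out[s] += 1
        return out

    @property
    def n_total(self) -> int:
        return len(self.status)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def read_statements(path: str | Path) -> StatementSet:
    """Read ``statement_id,text`` rows into a StatementSet (order preserved)."""
    df = _read_csv(path, ["statement_id", "text"])
    if df.empty:
        raise SchemaError(f"{path}: no statement rows")
    try:
        ids = df["statement_id"].astype(int)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-integer statement_id ({exc})") from None
    return StatementSet(tuple(zip(ids, df["text"])))


def write_statements(statements: StatementSet, path: str | Path) -> None:
    pd.DataFrame(statements.entries, columns=["statement_id", "text"]).to_csv(
        path, index=False, encoding="utf-8"
    )


def read_sorts(path: str | Path, statements: StatementSet) -> list[SortRecord]:
    """Read long-format ``participant_id,pile_label,statement_id`` sorts."""
    df = _read_csv(path, ["participant_id", "pile_label", "statement_id"])
    try:
        df["statement_id"] = df["statement_id"].astype(int)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-integer statement_id ({exc})") from None
    known = set(statements.ids)
    unknown = sorted(set(df["statement_id"]) - known)
    if unknown:
        raise ReferentialError(f"{path}: unknown statement ids {unknown}")
    records: list[SortRecord] = []
    for pid, grp in df.groupby("participant_id", sort=False):
        piles = tuple(
            (label, frozenset(sub["statement_id"]))
            for label, sub in grp.groupby("pile_label", sort=False)
        )
        records.append(SortRecord(str(pid), piles))
    return records


def write_sorts(sorts: Iterable[SortRecord], path: str | Path) -> None:
    rows = [
        (rec.participant_id, label, sid)
        for rec in sorts
        for label, members in rec.piles
        for sid in sorted(members)
    ]
    pd.DataFrame(rows, columns=["participant_id", "pile_label", "statement_id"]).to_csv(
        path, index=False, encoding="utf-8"
    )


def read_ratings(
    path: str | Path, statements: StatementSet, scale: RatingScale | None = None
) -> RatingTable:
    """Read ``participant_id,statement_id,rating`` rows against a scale."""
    scale = scale or RatingScale()
    df = _read_csv(path, ["participant_id", "statement_id", "rating"])
    for col in ("statement_id", "rating"):
        try:
            df[col] = df[col].astype(int)
        except ValueError as exc:
            raise SchemaError(f"{path}: non-integer {col} ({exc})") from None
    unknown = sorted(set(df["statement_id"]) - set(statements.ids))
    if unknown:
        raise ReferentialError(f"{path}: unknown statement ids {unknown}")
    out_of_range = df[~df["rating"].between(scale.min_code, scale.max_code)]
    if not out_of_range.empty:
        rownum = int(out_of_range.index[0]) + 2  # header + 1-based
        raise RangeError(
            f"{path}: row {rownum}: rating {out_of_range.iloc[0]['rating']} outside "
            f"scale [{scale.min_code}, {scale.max_code}]"
        )
    df["participant_id"] = df["participant_id"].astype(str)
    return RatingTable(df[["participant_id", "statement_id", "rating"]], scale)


def write_ratings(ratings: RatingTable, path: str | Path) -> None:
    ratings.records.to_csv(path, index=False, encoding="utf-8")


def read_participants(
    path: str | Path, vocabularies: Mapping[str, Sequence[str]] | None = None
) -> ParticipantTable:
    """Read the participant attribute table, optionally enforcing vocabularies.

    ``vocabularies`` maps attribute column -> allowed values; the empty
    string is always accepted as a missing-value marker.
    """
    df = _read_csv(path, ["participant_id"])
    if df.columns[0] != "participant_id":
        raise SchemaError(f"{path}: header must start with participant_id")
    if vocabularies:
        for col, allowed in vocabularies.items():
            if col not in df.columns:
                continue
            bad = df[~df[col].isin(list(allowed) + [""])]
            if not bad.empty:
                raise VocabularyError(
                    f"{path}: value {bad.iloc[0][col]!r} not in vocabulary for "
                    f"{col!r} (allowed: {sorted(allowed)})"
                )
    return ParticipantTable(df)


def write_participants(participants: ParticipantTable, path: str | Path) -> None:
    participants.table.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Sort validation
# ---------------------------------------------------------------------------


def validate_sorts(
    sorts: Sequence[SortRecord],
    statements: StatementSet,
    policy: SortPolicy | None = None,
) -> ValidationReport:
    """Classify each sorter as accepted, rejected, or incomplete.

    Rejection follows the study's sorting rules: a single pile containing
    everything, or a near-total singleton sort, is not a meaningful
    grouping.  Incomplete sorts cover only part of the statement set.
    Problems are reported, never raised; only accepted records flow into
    the similarity analysis.
    """
    policy = policy or SortPolicy()
    full = frozenset(statements.ids)
    status: dict[str, str] = {}
    reasons: dict[str, tuple[str, ...]] = {}
    accepted: list[SortRecord] = []
    for rec in sorts:
        codes: list[str] = []
        if rec.sorted_ids != full:
            status[rec.participant_id] = INCOMPLETE
            reasons[rec.participant_id] = (INCOMPLETE_CODE,)
            continue
        n_piles = len(rec.piles)
        n_singletons = sum(1 for _, m in rec.piles if len(m) == 1)
        if policy.one_pile and n_piles == 1:
            codes.append(ALL_ONE_PILE)
        if (
            n_piles > 1
            and n_singletons >= policy.singleton_fraction * n_piles
            and n_piles >= policy.singleton_pile_ratio * len(statements)
        ):
            codes.append(ALL_SINGLETONS)
        if codes:
            status[rec.participant_id] = REJECTED
            reasons[rec.participant_id] = tuple(codes)
        else:
            status[rec.participant_id] = ACCEPTED
            reasons[rec.participant_id] = ()
            accepted.append(rec)
    report = ValidationReport(status, reasons, tuple(accepted))
    c = report.counts
    logger.info(
        "sort validation: %d accepted, %d rejected, %d incomplete",
        c[ACCEPTED], c[REJECTED], c[INCOMPLETE],
    )
    return report


# ---------------------------------------------------------------------------
# Packaged reference fixtures (published cluster solution and ratings table)
# ---------------------------------------------------------------------------

_DATA_DIR = Path(__file__).parent / "data"


def load_reference_table(which: str = "statements") -> pd.DataFrame:
    """Load a packaged reference table.

    ``statements``: 79 statements with final cluster assignment and the
    published per-statement importance mean and SD.  ``top10``: the ten
    highest-rated statements in published order.
    """
    name = {"statements": "table2_statements.csv", "top10": "table3_top10.csv"}[which]
    df = pd.read_csv(_DATA_DIR / name, encoding="utf-8")
    return df
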