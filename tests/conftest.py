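"""Shared fixtures: reference tables, small constructed studies."""

from __future__ import annotations

import pandas as pd
import pytest

import gcmkit as g
from gcmkit.pipeline import _solution_from_table

# Published cluster mean importance ratings (to two decimals), by label.
PUBLISHED_CLUSTER_MEANS = {
    "The client": 3.36,
    "Treatment process": 3.15,
    "Treatment organisation": 3.30,
    "The clinician": 3.17,
    "Interaction client clinician": 3.42,
    "Clinician's adherence to good practice": 3.29,
    "Drug treatment": 3.54,
    "Pre-condition": 1.84,
    "Supporting activities": 2.82,
    "Supportive work and home life": 2.96,
}


@pytest.fixture(scope="session")
def ref_statements() -> pd.DataFrame:
    return g.load_reference_table("statements")


@pytest.fixture(scope="session")
def ref_solution(ref_statements):
    return _solution_from_table(ref_statements)


@pytest.fixture(scope="session")
def ref_stats(ref_statements):
    return g.stats_from_precomputed(ref_statements)


@pytest.fixture
def small_statements() -> g.StatementSet:
    return g.StatementSet(tuple((i, f"statement {i}") for i in range(1, 7)))


def make_sort(pid: str, *piles) -> g.SortRecord:
    return g.SortRecord(
        pid, tuple((f"pile{k}", frozenset(p)) for k, p in enumerate(piles))
    )


@pytest.fixture(scope="session")
def default_study():
    return g.simulate_study(g.SyntheticConfig(seed=1))
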