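"""Generator correctness: noise channels, determinism, ground-truth metrics."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import gcmkit as g
from gcmkit.core_data import RatingScale
from gcmkit.synthetic_data import _substream


class TestSimulateSorter:
    def test_noiseless_sorter_reproduces_partition(self):
        planted = g.planted_partition(12, 3)
        rec = g.simulate_sorter(planted, 0.0, 0.0, 0.0, np.random.default_rng(0))
        piles = {frozenset(m) for _, m in rec.piles}
        expected = {
            frozenset(s for s, c in planted.items() if c == k) for k in (1, 2, 3)
        }
        assert piles == expected

    def test_full_mislabel_single_pile_is_fixed_point(self):
        planted = g.planted_partition(5, 1)
        rec = g.simulate_sorter(planted, 1.0, 0.0, 0.0, np.random.default_rng(0))
        assert len(rec.piles) == 1

    def test_within_cluster_preservation_matches_independent_oracle(self):
        """S=6, K=2, eps=0.5: fraction of within-cluster pairs kept matches
        a naive re-implementation of the mislabel process within 2 SE over
        2000 draws each."""
        planted = g.planted_partition(6, 2)
        within = [
            (a, b)
            for a in range(1, 7)
            for b in range(a + 1, 7)
            if planted[a] == planted[b]
        ]
        n_draws = 2000

        def fraction_package(rng):
            kept = 0
            for _ in range(n_draws):
                rec = g.simulate_sorter(planted, 0.5, 0.0, 0.0, rng)
                kept += sum(rec.pile_of(a) == rec.pile_of(b) for a, b in within)
            return kept / (n_draws * len(within))

        def fraction_oracle(rng):
            kept = 0
            for _ in range(n_draws):
                assign = dict(planted)
                piles = [1, 2]
                for s in sorted(assign):
                    if rng.random() < 0.5:
                        others = [p for p in piles if p != assign[s]]
                        assign[s] = others[int(rng.integers(len(others)))]
                kept += sum(assign[a] == assign[b] for a, b in within)
            return kept / (n_draws * len(within))

        f_pkg = fraction_package(np.random.default_rng(1))
        f_orc = fraction_oracle(np.random.default_rng(2))
        # each fraction averages n_draws * 6 Bernoulli pair outcomes
        se = np.sqrt(0.25 / n_draws)  # conservative per-draw SE bound
        assert abs(f_pkg - f_orc) < 2 * se * 2  # draws share a sorter: inflate

    def test_split_and_merge_change_pile_count(self):
        planted = g.planted_partition(12, 3)
        split = g.simulate_sorter(planted, 0.0, 1.0, 0.0, np.random.default_rng(3))
        assert len(split.piles) == 4
        merge = g.simulate_sorter(planted, 0.0, 0.0, 1.0, np.random.default_rng(3))
        assert len(merge.piles) == 2


class TestSimulateRater:
    def test_noiseless_integer_importances_identity(self):
        imp = {1: 2.0, 2: 4.0, 3: 1.0}
        out = g.simulate_rater(imp, 0.0, 0.0, RatingScale(), np.random.default_rng(0))
        assert out == {1: 2, 2: 4, 3: 1}

    def test_clamped_to_scale(self):
        out = g.simulate_rater(
            {1: 9.0, 2: -3.0}, 0.0, 0.0, RatingScale(), np.random.default_rng(0)
        )
        assert out == {1: 4, 2: 1}

    def test_law_of_large_numbers_mean(self):
        rng = np.random.default_rng(1)
        vals = [
            g.simulate_rater({1: 2.5}, 0.0, 0.5, RatingScale(), rng)[1]
            for _ in range(200)
        ]
        assert abs(np.mean(vals) - 2.5) < 0.1


class TestSimulateStudy:
    def test_default_study_passes_validation(self, default_study):
        report = g.validate_sorts(default_study.sorts, default_study.statements)
        assert report.counts["accepted"] == default_study.config.n_sorters

    def test_ratings_within_scale(self, default_study):
        r = default_study.ratings.records["rating"]
        assert r.min() >= 1 and r.max() <= 4

    def test_same_seed_identical_bundle(self):
        a = g.simulate_study(g.SyntheticConfig(seed=5))
        b = g.simulate_study(g.SyntheticConfig(seed=5))
        assert a.sorts == b.sorts
        assert a.ratings.records.equals(b.ratings.records)
        assert a.participants.table.equals(b.participants.table)

    def test_adding_raters_keeps_sorter_draws(self):
        a = g.simulate_study(g.SyntheticConfig(seed=5))
        b = g.simulate_study(g.SyntheticConfig(seed=5, n_raters=35))
        assert a.sorts == b.sorts

    def test_invalid_configs_error(self):
        with pytest.raises(ValueError):
            g.SyntheticConfig(n_sorters=0)
        with pytest.raises(ValueError):
            g.SyntheticConfig(S=3, K=5)
        with pytest.raises(ValueError):
            g.SyntheticConfig(epsilon=1.5)
        with pytest.raises(ValueError):
            g.SyntheticConfig(cluster_effects=(3.0,))  # needs K entries

    def test_substreams_are_distinct(self):
        a = _substream(1, 1, 0).integers(0, 10**9, 5)
        b = _substream(1, 1, 1).integers(0, 10**9, 5)
        assert not np.array_equal(a, b)

    def test_written_study_reads_back(self, tmp_path, default_study):
        g.write_study(default_study, tmp_path)
        stmts = g.read_statements(tmp_path / "statements.csv")
        assert stmts.ids == default_study.statements.ids
        sorts = g.read_sorts(tmp_path / "sorts.csv", stmts)
        assert {r.participant_id for r in sorts} == {
            r.participant_id for r in default_study.sorts
        }
        ratings = g.read_ratings(tmp_path / "ratings.csv", stmts)
        assert len(ratings.records) == len(default_study.ratings.records)
        assert (tmp_path / "truth.json").exists()

    def test_subgroup_shift_moves_subgroup_means(self):
        cfg = g.SyntheticConfig(
            seed=3,
            n_sorters=1,
            n_raters=40,
            subgroup_shifts={"symptom_severity": {"none": -1.0}},
        )
        study = g.simulate_study(cfg)
        table = study.participants.table.set_index("participant_id")
        none_ids = [p for p in study.ratings.participants if table.loc[p, "symptom_severity"] == "none"]
        other_ids = [p for p in study.ratings.participants if p not in none_ids]
        m_none = g.statement_stats(study.ratings, none_ids, "none").table["mean"].mean()
        m_other = g.statement_stats(study.ratings, other_ids, "rest").table["mean"].mean()
        assert m_none < m_other - 0.3


class TestRecoveryAri:
    def test_identical_partitions(self):
        p = {1: 1, 2: 1, 3: 2}
        assert g.recovery_ari(p, p) == 1.0

    def test_one_cluster_versus_singletons(self):
        a = {i: 1 for i in range(1, 7)}
        b = {i: i for i in range(1, 7)}
        assert g.recovery_ari(a, b) == 0.0

    def test_hand_computed_contingency_value(self):
        """{12|34|56} vs {12|3|456}: ARI = (2 - 0.8) / (3.5 - 0.8) = 1.2/2.7."""
        a = {1: 1, 2: 1, 3: 2, 4: 2, 5: 3, 6: 3}
        b = {1: 1, 2: 1, 3: 2, 4: 3, 5: 3, 6: 3}
        assert g.recovery_ari(a, b) == pytest.approx(1.2 / 2.7, abs=1e-12)

    def test_matches_sklearn_on_random_partitions(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            la = rng.integers(0, 4, 15)
            lb = rng.integers(0, 4, 15)
            a = {i: int(la[i]) for i in range(15)}
            b = {i: int(lb[i]) for i in range(15)}
            assert g.recovery_ari(a, b) == pytest.approx(
                adjusted_rand_score(la, lb), abs=1e-12
            )

    def test_mismatched_statement_sets_error(self):
        with pytest.raises(ValueError):
            g.recovery_ari({1: 1}, {2: 1})
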