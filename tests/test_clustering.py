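"""Ward trees, cluster solutions, expert moves, bridging values."""

import numpy as np
import pytest

import gcmkit as g
from gcmkit.clustering import read_moves, reference_expert_moves
from gcmkit.point_map import PointMap
from gcmkit.similarity import SimilarityMatrix


def pm_from(coords):
    coords = np.asarray(coords, dtype=float)
    return PointMap(
        coordinates=coords,
        ids=tuple(range(1, len(coords) + 1)),
        stress=0.0,
        seed=0,
        n_restarts=1,
        iterations=0,
        converged=True,
    )


def naive_ward(points):
    """O(S^3) Lance-Williams agglomerator; merge heights for comparison.

    Maintains squared Ward distances and always merges the closest pair,
    breaking exact ties by lowest index pair.
    """
    points = np.asarray(points, dtype=float)
    clusters = {i: [i] for i in range(len(points))}
    d2 = {}
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            d2[(i, j)] = float(np.sum((points[i] - points[j]) ** 2))
    heights = []
    next_id = len(points)
    sizes = {i: 1 for i in clusters}
    while len(clusters) > 1:
        (a, b), best = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(np.sqrt(best))
        na, nb = sizes[a], sizes[b]
        new = next_id
        next_id += 1
        for c in list(clusters):
            if c in (a, b):
                continue
            nc = sizes[c]
            dac = d2[tuple(sorted((a, c)))]
            dbc = d2[tuple(sorted((b, c)))]
            dab = d2[(a, b)]
            d2[(c, new)] = (
                (na + nc) * dac + (nb + nc) * dbc - nc * dab
            ) / (na + nb + nc)
        clusters[new] = clusters.pop(a) + clusters.pop(b)
        sizes[new] = na + nb
        d2 = {k: v for k, v in d2.items() if a not in k and b not in k}
    return np.array(heights)


def two_blob_map():
    rng = np.random.default_rng(0)
    blob_a = rng.normal([0, 0], 0.1, size=(4, 2))
    blob_b = rng.normal([5, 5], 0.1, size=(4, 2))
    return pm_from(np.vstack([blob_a, blob_b]))


class TestWardTree:
    def test_last_merge_joins_separated_blobs(self):
        tree = g.ward_tree(two_blob_map())
        heights = tree.merges[:, 2]
        assert heights[-1] > 10 * heights[-2]  # blob join towers over the rest

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_heights_match_naive_agglomerator(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 2))
        tree = g.ward_tree(pm_from(pts))
        np.testing.assert_allclose(tree.merges[:, 2], naive_ward(pts), atol=1e-10)

    def test_duplicate_points_merge_at_zero(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
        tree = g.ward_tree(pm_from(pts))
        assert tree.merges[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(42)
        tree = g.ward_tree(pm_from(rng.normal(size=(15, 2))))
        assert np.all(np.diff(tree.merges[:, 2]) >= -1e-12)


class TestCutToSolution:
    def test_extreme_cuts(self):
        tree = g.ward_tree(two_blob_map())
        singletons = g.cut_to_solution(tree, 8)
        assert all(len(singletons.members(c)) == 1 for c in singletons.cluster_ids)
        one = g.cut_to_solution(tree, 1)
        assert one.members(1) == tuple(range(1, 9))

    def test_two_blob_recovery(self):
        sol = g.cut_to_solution(g.ward_tree(two_blob_map()), 2)
        assert sol.members(1) == (1, 2, 3, 4)
        assert sol.members(2) == (5, 6, 7, 8)

    def test_cut_refines_coarser_cut(self):
        rng = np.random.default_rng(8)
        tree = g.ward_tree(pm_from(rng.normal(size=(12, 2))))
        for k in range(3, 9):
            fine = g.cut_to_solution(tree, k)
            coarse = g.cut_to_solution(tree, k - 1)
            # every fine cluster lies wholly inside one coarse cluster
            for cid in fine.cluster_ids:
                parents = {coarse.assignment[s] for s in fine.members(cid)}
                assert len(parents) == 1

    @pytest.mark.parametrize("k", [0, 9])
    def test_out_of_range_k_errors(self, k):
        tree = g.ward_tree(two_blob_map())
        with pytest.raises(ValueError):
            g.cut_to_solution(tree, k)


class TestApplyMoves:
    def test_empty_move_list_is_identity(self, ref_solution):
        assert g.apply_moves(ref_solution, []).assignment == dict(
            ref_solution.assignment
        )

    def test_reference_moves_restore_published_assignment(self, ref_solution):
        """Undo the three published expert moves, re-apply them, and recover
        the published cluster table exactly."""
        label_ids = ref_solution.label_to_id()
        pre_moves = [
            (17, label_ids["The clinician"]),
            (48, label_ids["Drug treatment"]),
            (36, label_ids["Drug treatment"]),
        ]
        original = g.apply_moves(ref_solution, pre_moves)
        assert original.assignment[17] == label_ids["The clinician"]
        restored = g.apply_moves(original, reference_expert_moves())
        assert restored.assignment == dict(ref_solution.assignment)
        assert restored.assignment[17] == label_ids["Interaction client clinician"]

    def test_move_recorded_in_provenance(self, ref_solution):
        moved = g.apply_moves(ref_solution, [(17, "The clinician")])
        assert any("17" in p for p in moved.provenance)

    def test_unknown_targets_error(self, ref_solution):
        with pytest.raises(KeyError):
            g.apply_moves(ref_solution, [(17, "No such cluster")])
        with pytest.raises(KeyError):
            g.apply_moves(ref_solution, [(999, "The clinician")])

    def test_emptying_a_cluster_errors(self):
        sol = g.ClusterSolution(
            k=2, assignment={1: 1, 2: 2, 3: 2}, labels={1: "A", 2: "B"}
        )
        with pytest.raises(ValueError, match="empty"):
            g.apply_moves(sol, [(1, 2)])

    def test_moves_file_roundtrip(self, tmp_path):
        p = tmp_path / "moves.csv"
        p.write_text("statement_id,target_cluster_label\n17,The clinician\n")
        assert read_moves(p) == [(17, "The clinician")]


class TestBridging:
    def _T(self, matrix, ids):
        m = np.asarray(matrix, dtype=np.int64)
        return SimilarityMatrix(m, ids, n_sorters=int(m.max()))

    def test_minmax_endpoints(self):
        """A statement co-sorted only with its nearest neighbour gets 0; one
        co-sorted only with the farthest point gets 1."""
        pm = pm_from([[0, 0], [1, 0], [5, 0], [6, 0]])
        # statement 2's only link is its neighbour 1 (distance 1); statement
        # 4's only link is the farthest statement 1 (distance 6)
        T = self._T(
            [
                [3, 3, 0, 3],
                [3, 3, 0, 0],
                [0, 0, 3, 0],
                [3, 0, 0, 3],
            ],
            (1, 2, 3, 4),
        )
        res = g.bridging_values(pm, T)
        assert res.values[2] == 0.0  # only link is its neighbour 1 at distance 1
        assert res.values[4] == 1.0  # only link is statement 1 at distance 6

    def test_hand_computed_weighted_means(self):
        pm = pm_from([[0, 0], [1, 0], [0, 2], [3, 0]])
        W = np.array(
            [
                [0, 2, 1, 0],
                [2, 0, 0, 1],
                [1, 0, 0, 1],
                [0, 1, 1, 0],
            ]
        )
        T = self._T(W + np.diag([2, 2, 2, 2]), (1, 2, 3, 4))
        dist = pm.distances()
        expected_raw = [
            float(W[i] @ dist[i]) / W[i].sum() for i in range(4)
        ]
        res = g.bridging_values(pm, T)
        for sid, raw in zip((1, 2, 3, 4), expected_raw):
            assert res.raw[sid] == pytest.approx(raw, abs=1e-12)
        lo, hi = min(expected_raw), max(expected_raw)
        for sid, raw in zip((1, 2, 3, 4), expected_raw):
            assert res.values[sid] == pytest.approx((raw - lo) / (hi - lo), abs=1e-12)

    def test_uniform_weights_on_regular_polygon_all_zero(self):
        angles = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        pm = pm_from(np.c_[np.cos(angles), np.sin(angles)])
        T = self._T(np.full((6, 6), 2), tuple(range(1, 7)))
        res = g.bridging_values(pm, T)
        assert all(v == 0.0 for v in res.values.values())

    def test_isolated_statement_flagged(self):
        pm = pm_from([[0, 0], [1, 0], [2, 0]])
        T = self._T([[2, 2, 0], [2, 2, 0], [0, 0, 2]], (1, 2, 3))
        res = g.bridging_values(pm, T)
        assert res.isolated == (3,)
        assert res.raw[3] == pytest.approx((2 + 1) / 2)  # mean distance fallback

    def test_invariant_under_isometry(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 2))
        W = rng.integers(0, 5, size=(6, 6))
        W = W + W.T
        np.fill_diagonal(W, 6)
        T = self._T(W, tuple(range(1, 7)))
        theta = 1.1
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        a = g.bridging_values(pm_from(pts), T)
        b = g.bridging_values(pm_from(pts @ R + [3, -1]), T)
        for sid in a.values:
            assert a.values[sid] == pytest.approx(b.values[sid], abs=1e-10)

    def test_cluster_mean_bridging(self):
        pm = pm_from([[0, 0], [0.1, 0], [5, 0], [5.1, 0]])
        W = np.array([[0, 3, 1, 0], [3, 0, 0, 0], [1, 0, 0, 3], [0, 0, 3, 0]])
        T = self._T(W + np.diag([3] * 4), (1, 2, 3, 4))
        sol = g.ClusterSolution(
            k=2, assignment={1: 1, 2: 1, 3: 2, 4: 2}, labels={1: "A", 2: "B"}
        )
        res = g.bridging_values(pm, T, sol)
        assert res.cluster_means[1] == pytest.approx(
            (res.values[1] + res.values[2]) / 2
        )
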