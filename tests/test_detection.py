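"""Connected components, centroids, Hungarian matching, and metric formulas."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swinpick.detection import (
    centroids,
    connected_components,
    hungarian_match,
    metrics_from_counts,
    size_filter,
)
from swinpick.io import Volume, particle_table

# ---------------------------------------------------------------------------
# flood-fill oracle
# ---------------------------------------------------------------------------

_NEIGHBOURS = {
    6: [d for d in itertools.product((-1, 0, 1), repeat=3) if sum(map(abs, d)) == 1],
    18: [d for d in itertools.product((-1, 0, 1), repeat=3) if 1 <= sum(map(abs, d)) <= 2],
    26: [d for d in itertools.product((-1, 0, 1), repeat=3) if any(d)],
}


def flood_fill_components(data: np.ndarray, connectivity: int):
    """Brute-force component extraction by BFS, per class."""
    seen = np.zeros(data.shape, dtype=bool)
    comps = []
    for idx in np.ndindex(data.shape):
        if seen[idx] or data[idx] <= 0:
            continue
        cls = data[idx]
        stack, members = [idx], []
        seen[idx] = True
        while stack:
            cur = stack.pop()
            members.append(cur)
            for d in _NEIGHBOURS[connectivity]:
                nb = tuple(c + o for c, o in zip(cur, d))
                if all(0 <= c < s for c, s in zip(nb, data.shape)):
                    if not seen[nb] and data[nb] == cls:
                        seen[nb] = True
                        stack.append(nb)
        comps.append((int(cls), frozenset(members)))
    return comps


def brute_force_match(pred: np.ndarray, gt: np.ndarray, d_max: float):
    """Exhaustive search over injective assignments; returns (TP, total dist)."""
    if len(pred) == 0 or len(gt) == 0:
        return 0, 0.0
    dist = np.sqrt(((pred[:, None] - gt[None, :]) ** 2).sum(axis=2))
    best = (0, 0.0)
    n_p, n_g = len(pred), len(gt)
    small, large = (range(n_p), range(n_g)) if n_p <= n_g else (range(n_g), range(n_p))
    for subset in itertools.permutations(large, len(list(small))):
        tp, total = 0, 0.0
        for a, b in zip(small, subset):
            d = dist[a, b] if n_p <= n_g else dist[b, a]
            if d <= d_max:
                tp += 1
                total += d
        if tp > best[0] or (tp == best[0] and (tp == 0 or total < best[1])):
            best = (tp, total)
    return best


# ---------------------------------------------------------------------------


class TestConnectedComponents:
    def test_face_neighbours_form_one_component(self):
        data = np.zeros((4, 4, 4), dtype=np.int64)
        data[1, 1, 1] = data[1, 1, 2] = 1
        cs = connected_components(Volume(data), 18)
        assert len(cs.components) == 1 and cs.components[0].size == 2

    def test_corner_neighbours_split_under_18_join_under_26(self):
        data = np.zeros((4, 4, 4), dtype=np.int64)
        data[1, 1, 1] = data[2, 2, 2] = 1
        assert len(connected_components(Volume(data), 18).components) == 2
        assert len(connected_components(Volume(data), 26).components) == 1

    def test_edge_neighbours_join_under_18_split_under_6(self):
        data = np.zeros((4, 4, 4), dtype=np.int64)
        data[1, 1, 1] = data[1, 2, 2] = 1
        assert len(connected_components(Volume(data), 18).components) == 1
        assert len(connected_components(Volume(data), 6).components) == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle_on_random_fixtures(self, connectivity, rng):
        for _ in range(100):
            data = (rng.random((8, 8, 8)) < 0.3).astype(np.int64) * rng.integers(
                1, 4, size=(8, 8, 8)
            )
            ours = connected_components(Volume(data), connectivity)
            oracle = flood_fill_components(data, connectivity)
            assert len(ours.components) == len(oracle)
            assert sorted((c.class_id, c.size) for c in ours.components) == sorted(
                (cls, len(m)) for cls, m in oracle
            )

    def test_non_integer_volume_rejected(self):
        with pytest.raises(ValueError):
            connected_components(Volume(np.zeros((3, 3, 3), dtype=np.float32)), 18)


class TestSizeFilterAndCentroids:
    def _components(self, rng):
        data = np.zeros((12, 12, 12), dtype=np.int64)
        data[1, 1, 1] = 1  # size 1
        data[4, 4, 2:7] = 1  # size 5
        data[8:10, 3:8, 3:8] = 2  # size 50
        return connected_components(Volume(data), 18)

    def test_min_size_zero_is_identity(self, rng):
        cs = self._components(rng)
        assert size_filter(cs, 0).sizes() == cs.sizes()

    def test_inclusive_boundary(self, rng):
        cs = self._components(rng)
        assert sorted(size_filter(cs, 5).sizes()) == [5, 50]

    def test_survivors_monotone_in_min_size(self, rng):
        cs = self._components(rng)
        counts = [len(size_filter(cs, m).components) for m in range(0, 60, 5)]
        assert counts == sorted(counts, reverse=True)

    def test_single_voxel_centroid(self):
        data = np.zeros((8, 8, 8), dtype=np.int64)
        data[5, 4, 3] = 2  # canonical (z, y, x)
        table = centroids(connected_components(Volume(data), 18))
        assert table.iloc[0].tolist() == [2, 3.0, 4.0, 5.0]  # (x, y, z)

    def test_symmetric_cube_centroid(self):
        data = np.zeros((21, 21, 21), dtype=np.int64)
        data[9:12, 9:12, 9:12] = 1
        table = centroids(connected_components(Volume(data), 18))
        assert table.iloc[0].tolist() == [1, 10.0, 10.0, 10.0]

    def test_l_shape_centroid_hand_computed(self):
        data = np.zeros((8, 8, 8), dtype=np.int64)
        voxels = [(2, 2, 2), (2, 2, 3), (2, 2, 4), (2, 3, 2)]
        for v in voxels:
            data[v] = 1
        table = centroids(connected_components(Volume(data), 18))
        zm, ym, xm = (np.mean([v[i] for v in voxels]) for i in range(3))
        assert table.iloc[0].tolist() == [1, xm, ym, zm]


class TestHungarianMatch:
    def test_perfect_prediction(self, rng):
        pts = rng.uniform(0, 50, size=(7, 3))
        t = particle_table([(1, *p) for p in pts])
        m = hungarian_match(t, t.copy(), d_max=5.0)
        assert (m.tp, m.fp, m.fn) == (7, 0, 0)
        assert m.precision == m.recall == m.f1 == 1.0
        assert m.ad == 0.0

    def test_empty_prediction(self):
        gt = particle_table([(1, 1.0, 2.0, 3.0), (1, 10.0, 10.0, 10.0)])
        m = hungarian_match(particle_table([]), gt, d_max=5.0)
        assert (m.tp, m.fp, m.fn) == (0, 0, 2)
        assert m.recall == 0.0 and m.precision is None and m.ad is None

    def test_matches_exhaustive_assignment_on_small_instances(self, rng):
        for trial in range(60):
            n_p, n_g = rng.integers(0, 6, size=2)
            pred = rng.uniform(0, 12, size=(n_p, 3))
            gt = rng.uniform(0, 12, size=(n_g, 3))
            m = hungarian_match(
                particle_table([(1, *p) for p in pred]),
                particle_table([(1, *g) for g in gt]),
                d_max=5.0,
            )
            tp_oracle, dist_oracle = brute_force_match(pred, gt, 5.0)
            assert m.tp == tp_oracle
            if m.tp:
                total = sum(d for _, _, d in m.matched_pairs)
                assert total == pytest.approx(dist_oracle, abs=1e-9)

    def test_count_identities_and_symmetry(self, rng):
        pred = particle_table([(1, *p) for p in rng.uniform(0, 20, size=(9, 3))])
        gt = particle_table([(1, *p) for p in rng.uniform(0, 20, size=(6, 3))])
        m = hungarian_match(pred, gt, d_max=5.0)
        assert m.tp + m.fp == len(pred) and m.tp + m.fn == len(gt)
        swapped = hungarian_match(gt, pred, d_max=5.0)
        assert swapped.tp == m.tp and swapped.fp == m.fn and swapped.fn == m.fp
        assert (swapped.ad is None) == (m.ad is None)
        if m.ad is not None:
            assert swapped.ad == pytest.approx(m.ad)

    def test_jitter_below_half_cutoff_keeps_all_matches(self, rng):
        # well-separated points jittered by < d_max/2 keep a one-to-one match
        grid = np.array([[x, y, z] for x in (5, 25, 45) for y in (5, 25) for z in (5, 45)])
        gt = particle_table([(1, *p) for p in grid])
        jitter = rng.uniform(-1.0, 1.0, size=grid.shape)  # |jitter| < 2.5 = d_max/2
        pred = particle_table([(1, *(p + j)) for p, j in zip(grid, jitter)])
        m = hungarian_match(pred, gt, d_max=5.0)
        assert m.tp == len(grid) and m.fp == 0 and m.fn == 0

    def test_per_class_restricts_matches(self):
        pred = particle_table([(1, 10.0, 10.0, 10.0)])
        gt = particle_table([(2, 10.0, 10.0, 10.0)])
        assert hungarian_match(pred, gt, d_max=5.0, per_class=True).tp == 0
        assert hungarian_match(pred, gt, d_max=5.0, per_class=False).tp == 1

    def test_beyond_cutoff_never_matches(self):
        pred = particle_table([(1, 0.0, 0.0, 0.0)])
        gt = particle_table([(1, 0.0, 0.0, 5.1)])
        m = hungarian_match(pred, gt, d_max=5.0)
        assert m.tp == 0 and m.fp == 1 and m.fn == 1


class TestMetricsFromCounts:
    def test_degenerate_counts_are_undefined_not_zero(self):
        precision, recall, f1, miss = metrics_from_counts(0, 0, 0)
        assert precision is None and recall is None and f1 is None and miss is None

    def test_known_count_triples(self):
        p, r, f1, miss = metrics_from_counts(2622, 104, 160)
        assert (round(p, 4), round(r, 4), round(f1, 4)) == (0.9618, 0.9425, 0.9521)
        assert round(miss, 4) == 0.0575
        p, r, f1, _ = metrics_from_counts(482, 68, 16)
        assert (round(p, 3), round(r, 3), round(f1, 2)) == (0.876, 0.968, 0.92)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_counts(-1, 0, 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(tp=st.integers(0, 5000), fp=st.integers(0, 5000), fn=st.integers(0, 5000))
    def test_ratio_identities_hold_for_all_counts(self, tp, fp, fn):
        precision, recall, f1, miss = metrics_from_counts(tp, fp, fn)
        if tp + fp:
            assert precision == pytest.approx(tp / (tp + fp))
        else:
            assert precision is None
        if tp + fn:
            assert recall == pytest.approx(tp / (tp + fn))
            assert miss == pytest.approx(1 - recall)
        else:
            assert recall is None and miss is None
        if precision is not None and recall is not None and precision + recall > 0:
            assert f1 == pytest.approx(2 * precision * recall / (precision + recall))
            assert min(precision, recall) <= f1 <= max(precision, recall)
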