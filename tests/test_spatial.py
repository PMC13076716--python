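"""Spatial weights and Moran's i: brute-force oracles, defining
invariants, permutation-test behaviour, and serialization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import vapegeo as vg
from vapegeo.spatial import SpatialWeights, UndefinedStatisticError


def _geo(coords, ids=None):
    coords = np.asarray(coords, dtype=float)
    ids = ids or [f"D{i:02d}" for i in range(len(coords))]
    return pd.DataFrame({"division_id": ids, "x": coords[:, 0], "y": coords[:, 1]})


def _brute_knn(coords, ids, k):
    """O(n^2) oracle: sort all pairs by (distance, id)."""
    sets = {}
    for i, ci in enumerate(coords):
        cand = sorted(
            (np.hypot(*(ci - cj)), ids[j])
            for j, cj in enumerate(coords)
            if j != i
        )
        sets[ids[i]] = {d for _, d in cand[:k]}
    return sets


def _brute_moran(x, W):
    n = len(x)
    z = x - x.mean()
    num = sum(W[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return n / W.sum() * num / (z @ z)


class TestKnnWeights:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(size=(10, 2))
        geo = _geo(coords)
        w = vg.knn_weights(geo, 3)
        oracle = _brute_knn(coords, list(geo["division_id"]), 3)
        for d in geo["division_id"]:
            assert set(w.neighbours(d)) == oracle[d]

    def test_collinear_endpoints_pick_interior(self):
        geo = _geo([(0, 0), (1, 0), (2, 0), (3, 0)])
        w = vg.knn_weights(geo, 1)
        assert set(w.neighbours("D00")) == {"D01"}
        assert set(w.neighbours("D03")) == {"D02"}
        assert np.allclose(w.row_sums(), 1.0)

    @given(
        n=st.integers(5, 25),
        k=st.integers(1, 4),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_defining_invariants(self, n, k, seed):
        rng = np.random.default_rng(seed)
        geo = _geo(rng.uniform(size=(n, 2)))
        w = vg.knn_weights(geo, min(k, n - 1))
        assert w.W.diagonal().sum() == 0
        assert np.allclose(w.row_sums(), 1.0, atol=1e-12)
        assert (w.W.data > 0).all()

    def test_tie_break_is_lexicographic(self):
        # three equidistant candidates; the smaller id wins
        geo = _geo([(0, 0), (1, 0), (0, 1), (-1, 0)], ids=["A", "C", "B", "D"])
        w = vg.knn_weights(geo, 1)
        assert set(w.neighbours("A")) == {"B"}

    def test_k_out_of_range_rejected(self):
        geo = _geo([(0, 0), (1, 1)])
        with pytest.raises(ValueError):
            vg.knn_weights(geo, 2)
        with pytest.raises(ValueError):
            vg.knn_weights(geo, 0)

    def test_shuffled_input_rows_give_identical_weights(self):
        rng = np.random.default_rng(8)
        geo = _geo(rng.uniform(size=(20, 2)))
        shuffled = geo.sample(frac=1.0, random_state=3).reset_index(drop=True)
        w1, w2 = vg.knn_weights(geo, 3), vg.knn_weights(shuffled, 3)
        assert list(w1.ids) == list(w2.ids)
        assert (w1.W != w2.W).nnz == 0


class TestMoransI:
    def test_checkerboard_rook_lattice_is_minus_one(self):
        n = 4
        ids = [f"C{i}{j}" for i in range(n) for j in range(n)]
        W = np.zeros((16, 16))
        for i in range(n):
            for j in range(n):
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    if 0 <= i + di < n and 0 <= j + dj < n:
                        W[i * n + j, (i + di) * n + (j + dj)] = 1.0
        vals = np.array([(-1.0) ** (i + j) for i in range(n) for j in range(n)])
        sw = SpatialWeights(ids, W, spec="rook4x4")
        assert np.isclose(vg.morans_i(vals, sw), -1.0, atol=1e-12)

    @given(n=st.integers(4, 12), seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_double_sum(self, n, seed):
        rng = np.random.default_rng(seed)
        geo = _geo(rng.uniform(size=(n, 2)))
        w = vg.knn_weights(geo, min(3, n - 1))
        x = rng.normal(size=n)
        assert np.isclose(
            vg.morans_i(x, w), _brute_moran(x, w.W.toarray()), atol=1e-12
        )

    def test_affine_invariance(self):
        rng = np.random.default_rng(11)
        geo = _geo(rng.uniform(size=(30, 2)))
        w = vg.knn_weights(geo, 3)
        x = rng.normal(size=30)
        base = vg.morans_i(x, w)
        assert np.isclose(vg.morans_i(3.7 * x - 2.0, w), base, atol=1e-12)
        assert np.isclose(vg.morans_i(-0.5 * x + 10, w), base, atol=1e-12)

    def test_constant_values_error_not_nan(self):
        geo = _geo(np.random.default_rng(0).uniform(size=(10, 2)))
        w = vg.knn_weights(geo, 2)
        with pytest.raises(UndefinedStatisticError):
            vg.morans_i(np.full(10, 3.0), w)


class TestPermutationTest:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        geo = _geo(rng.uniform(size=(25, 2)))
        w = vg.knn_weights(geo, 3)
        x = rng.normal(size=25)
        r1 = vg.mc_permutation_test(x, w, n_sims=199, seed=5)
        r2 = vg.mc_permutation_test(x, w, n_sims=199, seed=5)
        assert r1 == r2

    def test_perfectly_clustered_surface_minimal_p(self):
        """Two separated spatial blocks of 0s and 1s: no permutation can
        score higher, so p = 1/(n_sims+1).  Each block is a line of
        equally spaced points, whose 2-NN graph admits I=1 only for
        block-constant assignments."""
        left = np.column_stack([np.arange(25.0), np.zeros(25)])
        right = left + np.array([100.0, 0.0])
        geo = _geo(np.vstack([left, right]))
        vals = np.r_[np.zeros(25), np.ones(25)]
        w = vg.knn_weights(geo, 2)
        r = vg.mc_permutation_test(vals, w, n_sims=199, seed=0)
        assert r.p_value == 1 / 200

    def test_pseudo_p_in_range(self):
        rng = np.random.default_rng(6)
        geo = _geo(rng.uniform(size=(20, 2)))
        w = vg.knn_weights(geo, 3)
        for seed in range(10):
            r = vg.mc_permutation_test(rng.normal(size=20), w, n_sims=99, seed=seed)
            assert 0 < r.p_value <= 1

    def test_too_few_sims_rejected(self):
        geo = _geo(np.random.default_rng(0).uniform(size=(10, 2)))
        w = vg.knn_weights(geo, 2)
        with pytest.raises(ValueError):
            vg.mc_permutation_test(np.arange(10.0), w, n_sims=10)

    def test_callable_statistic_agrees_with_fast_path(self):
        rng = np.random.default_rng(13)
        geo = _geo(rng.uniform(size=(15, 2)))
        w = vg.knn_weights(geo, 3)
        x = rng.normal(size=15)
        fast = vg.mc_permutation_test(x, w, "morans_i", n_sims=99, seed=1)
        slow = vg.mc_permutation_test(x, w, vg.morans_i, n_sims=99, seed=1)
        assert np.isclose(fast.statistic, slow.statistic)
        assert fast.p_value == slow.p_value


class TestSelectWeights:
    def test_single_candidate_returned_unchanged(self):
        rng = np.random.default_rng(1)
        geo = _geo(rng.uniform(size=(20, 2)))
        w = vg.knn_weights(geo, 3)
        best, trials = vg.select_weights(rng.normal(size=20), [w], n_sims=49, seed=0)
        assert best is w and len(trials) == 1

    def test_reproducible_selection(self):
        rng = np.random.default_rng(5)
        geo = _geo(rng.uniform(size=(40, 2)))
        x = rng.normal(size=40)
        cands = [vg.knn_weights(geo, k) for k in (1, 3, 5)]
        b1, t1 = vg.select_weights(x, cands, n_sims=99, seed=7)
        b2, t2 = vg.select_weights(x, cands, n_sims=99, seed=7)
        assert b1.spec == b2.spec
        assert [t.p_value for t in t1] == [t.p_value for t in t2]

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValueError):
            vg.select_weights(np.arange(5.0), [], n_sims=49)


class TestSerialization:
    def test_edgelist_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(17)
        geo = _geo(rng.uniform(size=(30, 2)))
        w = vg.knn_weights(geo, 4)
        path = tmp_path / "w.tsv"
        w.to_edgelist(path)
        back = vg.SpatialWeights.from_edgelist(path)
        assert list(back.ids) == list(w.ids)
        assert back.spec == w.spec
        assert (back.W != w.W).nnz == 0  # exact, not approximate


def test_subset_restandardizes_rows():
    rng = np.random.default_rng(19)
    geo = _geo(rng.uniform(size=(20, 2)))
    w = vg.knn_weights(geo, 3)
    sub = w.subset(sorted(geo["division_id"][:12]))
    rs = sub.row_sums()
    assert ((np.isclose(rs, 1.0, atol=1e-12)) | (rs == 0)).all()
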