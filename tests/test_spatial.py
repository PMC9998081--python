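"""Spatial weights, local autocorrelation statistics, permutation
inference, FDR control and sliding-window aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldspot import (
    FeatureTrack,
    bh_fdr,
    build_weights,
    ca_coords,
    find_hotspots,
    getis_ord,
    local_moran,
    permutation_pvalues,
    sliding_window,
)
from foldspot.spatial import SpatialWeights, global_moran
from foldspot.synthetic import make_helix

from conftest import random_weights
from oracles import (
    brute_force_sliding,
    exact_conditional_pvalues,
    naive_bh,
    naive_getis,
    naive_global_moran,
    naive_local_moran,
)


class TestWeights:
    def test_binary_radius_collinear(self):
        coords = np.array([[0, 0, 0], [5, 0, 0], [10, 0, 0]], float)
        W = build_weights(coords, "binary_radius", radius=6.0)
        np.testing.assert_array_equal(W.w, [[0, 1, 0], [1, 0, 1], [0, 1, 0]])

    def test_decay_closed_form(self):
        coords = np.array([[0, 0, 0], [5, 0, 0], [10, 0, 0]], float)
        W = build_weights(coords, "decay", decay_scale=5.0)
        assert W.w[0, 1] == pytest.approx(np.exp(-1), abs=5e-5)
        assert W.w[0, 2] == pytest.approx(np.exp(-2), abs=5e-5)

    def test_knn_asymmetry(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [10, 0, 0]], float)
        W = build_weights(coords, "knn", k=1)
        assert W.w[2, 1] == 1 and W.w[1, 0] == 1 and W.w[1, 2] == 0
        assert not np.allclose(W.w, W.w.T)

    def test_knn_tie_breaks_by_lower_index(self):
        # residues 1 and 2 are equidistant from residue 0
        coords = np.array([[0, 0, 0], [1, 0, 0], [-1, 0, 0]], float)
        W = build_weights(coords, "knn", k=1)
        assert W.w[0, 1] == 1 and W.w[0, 2] == 0

    def test_row_standardization_and_self(self):
        coords = ca_coords(make_helix(10))
        W = build_weights(coords, "binary_radius", radius=8.0,
                          include_self=True, row_standardize=True)
        sums = W.w.sum(axis=1)
        np.testing.assert_allclose(sums[sums > 0], 1.0)
        assert (np.diag(W.w) > 0).all()

    def test_symmetry_before_standardization(self):
        coords = ca_coords(make_helix(15))
        for method in ("binary_radius", "decay"):
            W = build_weights(coords, method, radius=8.0, decay_scale=5.0)
            np.testing.assert_allclose(W.w, W.w.T)

    def test_parameter_validation(self):
        coords = np.eye(3)
        with pytest.raises(ValueError):
            build_weights(coords, "binary_radius", radius=-1)
        with pytest.raises(ValueError):
            build_weights(coords, "knn", k=3)
        with pytest.raises(ValueError):
            build_weights(coords, "decay", decay_scale=0)
        with pytest.raises(ValueError):
            build_weights(coords, "voronoi")

    def test_isolated_residue_warns_zero_row(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [100, 0, 0]], float)
        with pytest.warns(UserWarning, match="no neighbor"):
            W = build_weights(coords, "binary_radius", radius=5.0)
        assert W.w[2].sum() == 0


class TestGetisOrd:
    def test_zero_on_complete_self_inclusive_weights(self):
        rng = np.random.default_rng(7)
        for n in (5, 12, 30):
            W = SpatialWeights(np.ones((n, n)), "binary_radius", include_self=True)
            z = getis_ord(rng.random(n), W)
            np.testing.assert_allclose(z, 0.0, atol=1e-9)

    @pytest.mark.parametrize("include_self", [True, False])
    def test_matches_naive_closed_form(self, include_self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(4, 31))
            w = random_weights(rng, n)
            if include_self:
                np.fill_diagonal(w, 1.0)
            W = SpatialWeights(w, "decay", include_self=include_self)
            x = rng.random(n)
            np.testing.assert_allclose(
                getis_ord(x, W), naive_getis(x, w, include_self), atol=1e-10
            )

    def test_four_point_chain_toy(self):
        w = np.array(
            [[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]], float
        )
        x = np.array([1.0, 0.0, 0.0, 1.0])
        W = SpatialWeights(w, "binary_radius", include_self=False)
        np.testing.assert_allclose(
            getis_ord(x, W), naive_getis(x, w, False), atol=1e-10
        )

    def test_planted_blob_peaks_inside(self, helix60):
        x = np.zeros(60)
        x[20:30] = 1
        W = build_weights(ca_coords(helix60), "binary_radius", radius=8.0,
                          include_self=True)
        z = getis_ord(x, W)
        assert 20 <= int(np.argmax(z)) <= 29

    def test_constant_feature_rejected(self):
        W = SpatialWeights(np.ones((4, 4)), "binary_radius", include_self=True)
        with pytest.raises(ValueError, match="variance"):
            getis_ord(np.ones(4), W)

    def test_length_mismatch_rejected(self):
        W = SpatialWeights(np.ones((4, 4)), "binary_radius")
        with pytest.raises(ValueError):
            getis_ord(np.ones(5), W)


class TestLocalMoran:
    def test_matches_naive(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(4, 31))
            w = random_weights(rng, n)
            x = rng.random(n)
            W = SpatialWeights(w, "decay")
            np.testing.assert_allclose(
                local_moran(x, W), naive_local_moran(x, w), atol=1e-10
            )

    def test_sum_equals_s0_times_global(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(4, 25))
            w = random_weights(rng, n)
            x = rng.random(n)
            W = SpatialWeights(w, "decay")
            s0 = w.sum()
            lhs = local_moran(x, W).sum()
            rhs = s0 * naive_global_moran(x, w)
            assert lhs == pytest.approx(rhs, abs=1e-9)
            assert global_moran(x, W) == pytest.approx(
                naive_global_moran(x, w), abs=1e-10
            )

    def _chain_weights(self, n):
        w = np.zeros((n, n))
        for i in range(n - 1):
            w[i, i + 1] = w[i + 1, i] = 1.0
        return SpatialWeights(w, "binary_radius")

    def test_checkerboard_all_negative(self):
        W = self._chain_weights(10)
        x = np.array([1.0, 0.0] * 5)
        assert (local_moran(x, W) < 0).all()

    def test_two_halves_interior_positive(self):
        W = self._chain_weights(10)
        x = np.array([1.0] * 5 + [0.0] * 5)
        I = local_moran(x, W)
        interior = [1, 2, 3, 6, 7, 8]
        assert (I[interior] > 0).all()


class TestPermutation:
    def _toy(self):
        coords = np.array(
            [[0, 0, 0], [4, 0, 0], [8, 0, 0], [4, 4, 0], [8, 4, 0]], float
        )
        W = build_weights(coords, "binary_radius", radius=5.0, include_self=True)
        x = np.array([1.0, 1.0, 0.0, 1.0, 0.0])
        return x, W

    def test_bounds_and_determinism(self, helix60):
        x = np.zeros(60)
        x[10:16] = 1
        W = build_weights(ca_coords(helix60), "binary_radius", radius=8.0,
                          include_self=True)
        p1 = permutation_pvalues(x, W, n_perm=99, seed=7)
        p2 = permutation_pvalues(x, W, n_perm=99, seed=7)
        np.testing.assert_array_equal(p1, p2)
        assert (p1 >= 1 / 100).all() and (p1 <= 1).all()

    @pytest.mark.parametrize("method", ["getis_ord", "moran"])
    def test_monte_carlo_matches_exact_enumeration(self, method):
        x, W = self._toy()
        if method == "getis_ord":
            stat = lambda xv: getis_ord(xv, W)
        else:
            stat = lambda xv: local_moran(xv, W)
        exact = exact_conditional_pvalues(x, stat)
        mc = permutation_pvalues(x, W, method=method, n_perm=10_000, seed=3)
        np.testing.assert_allclose(mc, exact, atol=0.02)

    def test_null_pvalues_super_uniform(self, helix60):
        # exchangeable feature => P(p <= 0.05) should not exceed 0.05 by much
        W = build_weights(ca_coords(helix60), "binary_radius", radius=8.0,
                          include_self=True)
        rng = np.random.default_rng(123)
        hits = total = 0
        for _ in range(25):
            x = rng.permutation([1.0] * 10 + [0.0] * 50)
            p = permutation_pvalues(x, W, n_perm=199, seed=int(rng.integers(2**31)))
            hits += (p <= 0.05).sum()
            total += p.size
        assert hits / total <= 0.07

    def test_invalid_args(self):
        x, W = self._toy()
        with pytest.raises(ValueError):
            permutation_pvalues(x, W, n_perm=0)
        with pytest.raises(ValueError):
            permutation_pvalues(x, W, alternative="less-ish")


class TestBHFDR:
    def test_hand_evaluated_step_up(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        q, reject = bh_fdr(p, 0.05)
        assert reject.all()
        np.testing.assert_allclose(q, [0.05, 0.05, 0.05, 0.05, 0.05])

    def test_all_ones(self):
        q, reject = bh_fdr(np.ones(8), 0.05)
        assert not reject.any()
        np.testing.assert_allclose(q, 1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.001, 1.0, 40)
        perm = rng.permutation(40)
        q, _ = bh_fdr(p, 0.1)
        qp, _ = bh_fdr(p[perm], 0.1)
        np.testing.assert_allclose(qp, q[perm])

    def test_matches_naive_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        for _ in range(100):
            p = rng.uniform(1e-4, 1.0, int(rng.integers(3, 60)))
            q, reject = bh_fdr(p, 0.05)
            nq, nreject = naive_bh(p, 0.05)
            np.testing.assert_allclose(q, nq, atol=1e-12)
            np.testing.assert_array_equal(reject, nreject)
            sm_reject, sm_q, *_ = multipletests(p, 0.05, method="fdr_bh")
            np.testing.assert_allclose(q, sm_q, atol=1e-12)
            np.testing.assert_array_equal(reject, sm_reject)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.0, 0.5]), 0.05)
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.5]), 0.05)

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=50)
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_step_up_properties_on_arbitrary_pvectors(self, p_list):
        p = np.array(p_list)
        q, reject = bh_fdr(p, 0.05)
        nq, nreject = naive_bh(p, 0.05)
        np.testing.assert_allclose(q, nq, atol=1e-12)
        np.testing.assert_array_equal(reject, nreject)
        assert (q >= p / len(p) - 1e-12).all() and (q <= 1.0).all()
        # q preserves the ordering of p
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestFindHotspots:
    def test_paper_style_call(self, helix60):
        original = [20, 21, 22, 23, 24, 25, 26, 27, 28, 29]
        positive = [1 if i in original else 0 for i in range(len(helix60))]
        hotspots = find_hotspots(helix60, positive, false_discovery_rate=0.05)
        assert hotspots.fdr == 0.05
        assert len(hotspots) == 60
        assert (hotspots.q[hotspots.hot] <= 0.05).all()
        assert (hotspots.statistic[hotspots.hot] > 0).all()

    def test_planted_blob_recovered(self, helix60):
        x = np.zeros(60)
        x[20:30] = 1
        res = find_hotspots(helix60, x, false_discovery_rate=0.05, n_perm=999)
        hot = set(np.flatnonzero(res.hot))
        planted = set(range(20, 30))
        sensitivity = len(hot & planted) / len(planted)
        specificity = 1 - len(hot - planted) / 50
        assert sensitivity >= 0.8
        assert specificity >= 0.95

    def test_moran_variant_recovers_blob(self, helix60):
        x = np.zeros(60)
        x[20:30] = 1
        res = find_hotspots(helix60, x, method="moran", n_perm=499)
        hot = set(np.flatnonzero(res.hot))
        assert hot and hot <= set(range(15, 35))

    def test_rigid_motion_invariance(self, helix60):
        x = np.zeros(60)
        x[25:31] = 1
        base = find_hotspots(helix60, x, n_perm=199)
        coords = ca_coords(helix60)
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = coords @ R.T + np.array([12.0, -3.0, 40.0])
        rot = find_hotspots(moved, x, n_perm=199)
        np.testing.assert_array_equal(base.hot, rot.hot)
        np.testing.assert_allclose(base.p, rot.p)

    def test_bad_rate_rejected(self, helix60):
        with pytest.raises(ValueError):
            find_hotspots(helix60, np.arange(60.0), false_discovery_rate=1.5)


class TestSlidingWindow:
    def test_global_window_equals_global_mean(self, helix60):
        x = np.arange(60.0)
        out = sliding_window(helix60, x, radius=1e6, agg="mean")
        np.testing.assert_allclose(out.values, x.mean())

    def test_zero_radius_identity(self, helix60):
        x = np.arange(60.0)
        out = sliding_window(helix60, x, radius=0.0, agg="mean")
        np.testing.assert_allclose(out.values, x)

    @pytest.mark.parametrize("agg", ["mean", "sum", "max"])
    def test_matches_brute_force(self, helix60, agg):
        rng = np.random.default_rng(8)
        x = rng.random(60)
        out = sliding_window(helix60, x, radius=8.0, agg=agg)
        want = brute_force_sliding(ca_coords(helix60), x, 8.0, agg)
        np.testing.assert_array_equal(out.values, want)

    def test_named_track_input(self, helix60):
        track = FeatureTrack("signal", np.arange(60.0))
        out = sliding_window(helix60, track, radius=8.0, agg="sum")
        assert out.name.startswith("signal_sum")

    def test_unknown_agg_rejected(self, helix60):
        with pytest.raises(ValueError):
            sliding_window(helix60, np.arange(60.0), radius=5.0, agg="median")
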