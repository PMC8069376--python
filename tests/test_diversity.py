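"""Alpha/beta diversity closed forms, ordination, and recovery statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy import stats as sstats

from capturesim.diversity_quant import (
    RarefactionParams,
    alpha_diversity,
    beta_diversity,
    bray_curtis,
    chao1,
    coverage_curve,
    dendrogram_to_newick,
    filter_clusters,
    goods_coverage,
    hcluster,
    pcoa,
    ratio_of_logs,
    recovery_stats,
    shannon,
    simpson_1md,
)


class TestClosedForms:
    def test_hand_computed_fixture(self):
        counts = np.array([5, 3, 1, 1])
        # S=4, F1=2, F2=0 -> chao1 = 4 + 2*1/2 = 5; goods = 1 - 2/10
        assert chao1(counts) == 5.0
        assert goods_coverage(counts) == pytest.approx(0.8)

    def test_uniform_profile_extremes(self):
        even = np.full(8, 100)
        assert shannon(even) == pytest.approx(3.0)          # log2(8) bits
        assert simpson_1md(even) == pytest.approx(0.875)    # 1 - 1/8
        single = np.array([50])
        assert chao1(single) == 1.0
        assert shannon(single) == 0.0

    def test_chao1_lower_bound_and_ranges(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = rng.integers(0, 20, size=30)
            if c.sum() == 0:
                continue
            s_obs = int((c > 0).sum())
            assert chao1(c) >= s_obs
            f1 = int((c == 1).sum())
            if f1 <= 1:
                assert chao1(c) == pytest.approx(s_obs)
            assert 0 <= simpson_1md(c) <= 1
            assert 0 <= goods_coverage(c) <= 1
            assert shannon(c) <= np.log2(s_obs) + 1e-12

    def test_against_skbio_reference_implementations(self):
        from skbio.diversity import alpha as ska

        rng = np.random.default_rng(1)
        for _ in range(10):
            c = rng.integers(0, 50, size=25)
            c[0] = max(c[0], 1)
            assert chao1(c) == pytest.approx(ska.chao1(c, bias_corrected=True))
            assert simpson_1md(c) == pytest.approx(ska.simpson(c))
            assert goods_coverage(c) == pytest.approx(ska.goods_coverage(c))
            assert shannon(c, base=2) == pytest.approx(ska.shannon(c, base=2))


class TestAlphaRarefaction:
    def test_bootstrap_means_at_safe_depths(self):
        rng = np.random.default_rng(2)
        col = pd.Series(rng.integers(0, 400, size=60))
        params = RarefactionParams(depths=(250, 500), reps=30, seed=3)
        res = alpha_diversity(col, params)
        assert list(res.table.index) == [250, 500]
        assert (res.table["goods_coverage"] <= 1).all()
        # coverage grows with depth on average
        assert (res.table.loc[500, "goods_coverage"]
                >= res.table.loc[250, "goods_coverage"] - 0.02)

    def test_unattainable_depth_skipped(self):
        col = pd.Series([100, 100])
        params = RarefactionParams(depths=(150, 5000), reps=5, seed=4)
        res = alpha_diversity(col, params)
        assert list(res.table.index) == [150]
        with pytest.raises(ValueError):
            alpha_diversity(pd.Series([5]), RarefactionParams(depths=(10,), reps=2))

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(5)
        col = pd.Series(rng.integers(0, 300, size=40))
        perm = col.sample(frac=1.0, random_state=1).reset_index(drop=True)
        params = RarefactionParams(depths=(500,), reps=50, seed=6)
        a = alpha_diversity(col, params).table
        b = alpha_diversity(perm, params).table
        for m in ("chao1", "shannon", "simpson_1mD", "goods_coverage"):
            assert a.loc[500, m] == pytest.approx(b.loc[500, m], rel=0.05)


class TestBrayCurtis:
    def test_hand_computed_pair(self):
        t = pd.DataFrame({"x": [6, 0], "y": [2, 4]})
        assert bray_curtis(t).loc["x", "y"] == pytest.approx(1 - 2 * 2 / 12)

    def test_identical_and_disjoint_columns(self):
        t = pd.DataFrame({"a": [3, 1], "b": [3, 1], "c": [0, 9]})
        # zero-pad c's support so sums differ
        D = bray_curtis(pd.DataFrame({"a": [3, 1, 0], "b": [3, 1, 0], "c": [0, 0, 9]}))
        assert D.loc["a", "b"] == 0.0
        assert D.loc["a", "c"] == 1.0

    def test_metric_properties(self):
        rng = np.random.default_rng(7)
        t = pd.DataFrame(rng.integers(1, 50, size=(12, 5)))
        D = bray_curtis(t)
        arr = D.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)
        assert ((arr >= 0) & (arr <= 1)).all()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(pd.DataFrame({"a": [1, 2]}))
        with pytest.raises(ValueError):
            bray_curtis(pd.DataFrame({"a": [1, 2], "b": [0, 0]}))


class TestPcoa:
    def test_round_trips_euclidean_embeddable_distances(self):
        rng = np.random.default_rng(8)
        pts = rng.random((6, 2))
        D = pd.DataFrame(squareform(pdist(pts)))
        coords, eig, neg = pcoa(D)
        back = squareform(pdist(coords.to_numpy()))
        assert np.abs(back - D.to_numpy()).max() < 1e-9
        assert neg == pytest.approx(0.0, abs=1e-9)

    def test_equilateral_triangle_has_two_equal_axes(self):
        D = pd.DataFrame(1 - np.eye(3))
        _, eig, _ = pcoa(D)
        pos = np.sort(eig[eig > 1e-12])
        assert pos.size == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_negative_eigenvalues_zeroed_and_reported(self):
        # a non-Euclidean metric: two antipodal pairs on a 4-cycle
        D = pd.DataFrame(1.0 - np.eye(4))
        D.iloc[0, 1] = D.iloc[1, 0] = 2.0
        D.iloc[2, 3] = D.iloc[3, 2] = 2.0
        _, eig, neg = pcoa(D)
        assert (eig >= 0).all()
        assert neg == pytest.approx(1.0, abs=1e-9)

    def test_asymmetric_matrix_rejected(self):
        D = pd.DataFrame([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError):
            pcoa(D)


class TestHcluster:
    def test_identical_samples_merge_first_at_zero(self):
        t = pd.DataFrame({"a": [5, 1, 0], "b": [5, 1, 0], "c": [0, 0, 9]})
        D = bray_curtis(t)
        Z = hcluster(D)
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == 0.0

    def test_planted_two_group_top_split(self):
        rng = np.random.default_rng(9)
        base1 = rng.integers(50, 100, size=20)
        base2 = rng.integers(50, 100, size=20)
        cols = {}
        for i in range(3):
            cols[f"g1_{i}"] = base1 + rng.integers(0, 5, size=20)
        for i in range(3):
            cols[f"g2_{i}"] = np.concatenate([base2[10:], base2[:10]]) + rng.integers(0, 5, size=20)
        t = pd.DataFrame(cols)
        D = bray_curtis(t)
        Z = hcluster(D)
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(Z, t=2, criterion="maxclust")
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_single_sample_single_leaf_newick(self):
        Z = hcluster(pd.DataFrame([[0.0]], index=["s"], columns=["s"]))
        assert dendrogram_to_newick(Z, ["s"]) == "s;"

    def test_newick_contains_all_labels(self):
        t = pd.DataFrame(np.random.default_rng(10).integers(1, 20, size=(8, 4)),
                         columns=list("wxyz"))
        nwk = dendrogram_to_newick(hcluster(bray_curtis(t)), list("wxyz"))
        assert nwk.endswith(";")
        for lbl in "wxyz":
            assert lbl in nwk


class TestFilterClusters:
    def test_half_percent_display_floor(self):
        t = pd.DataFrame({
            "s1": [996, 4, 0],
            "s2": [994, 0, 6],
        }, index=["big", "low", "borderline"])
        out = filter_clusters(t, min_fraction=0.005)
        # 0.4% everywhere -> dropped; 0.6% in one sample -> kept
        assert "low" not in out.index
        assert "borderline" in out.index and "big" in out.index

    def test_retained_ordering_preserved_after_renormalization(self):
        rng = np.random.default_rng(11)
        t = pd.DataFrame({"s": rng.integers(1, 1000, size=30)})
        out = filter_clusters(t, 0.005)
        rel = out["s"] / out["s"].sum()
        order_before = out["s"].sort_values().index
        order_after = rel.sort_values().index
        assert list(order_before) == list(order_after)


class TestRecovery:
    def test_proportional_counts_give_perfect_r2(self):
        truth = pd.DataFrame({"h": [1e8] * 3, "m": [1e7] * 3, "l": [1e6] * 3,
                              "u": [0.0] * 3}, index=["a", "b", "c"])
        counts = (truth * 3.3e-4).round()
        stats = recovery_stats(truth, counts)
        assert np.allclose(stats.per_member_r2, 1.0)
        assert stats.pooled_spearman > 0.9

    def test_zero_variance_reported_missing(self):
        truth = pd.DataFrame({"a": [1.0, 1], "b": [1.0, 1], "c": [1.0, 1]},
                             index=["x", "y"])
        counts = pd.DataFrame({"a": [5, 2], "b": [6, 2], "c": [7, 2]},
                              index=["x", "y"])
        stats = recovery_stats(truth, counts)
        assert stats.per_member_r2.isna().all()

    def test_spearman_matches_naive_rank_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.random(15)
        y = x + rng.normal(0, 0.2, size=15)
        rho, _ = sstats.spearmanr(x, y)
        # naive O(n^2) rank computation
        rank = lambda v: np.array([(v < vi).sum() + 1 for vi in v], dtype=float)
        rx, ry = rank(x), rank(y)
        naive = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(naive, abs=1e-12)

    def test_ratio_of_logs_matches_printed_convention(self):
        # marker at 7.58 log10 copies over reference gene at 5.56 -> 1.36
        assert round(ratio_of_logs(7.58, 5.56), 2) == 1.36
        assert ratio_of_logs(0.0, 0.0) == 0.0


class TestCoverageCurve:
    def test_effort_equals_depth_at_unit_marker_fraction(self):
        rng = np.random.default_rng(13)
        col = pd.Series(rng.integers(0, 100, size=50))
        params = RarefactionParams(depths=(250, 500), reps=10, seed=14)
        cc = coverage_curve({"m": col}, {"m": 1.0}, params)
        assert (cc["effort"] == cc["depth"]).all()

    def test_zero_marker_fraction_rejected(self):
        col = pd.Series([100, 200])
        with pytest.raises(ValueError):
            coverage_curve({"m": col}, {"m": 0.0},
                           RarefactionParams(depths=(50,), reps=2))

    def test_enriched_method_needs_less_effort_for_same_coverage(self):
        # same mapped profile, 100x different on-target fraction
        rng = np.random.default_rng(15)
        col = pd.Series(rng.integers(0, 200, size=80))
        params = RarefactionParams(depths=(500, 1000), reps=10, seed=16)
        cc = coverage_curve({"cap": col, "sg": col}, {"cap": 0.9, "sg": 0.009}, params)
        cap = cc[cc["method"] == "cap"].set_index("depth")
        sg = cc[cc["method"] == "sg"].set_index("depth")
        assert (cap["effort"] * 99 < sg["effort"] + 1e-9).all()
        assert cap["goods_coverage"].equals(sg["goods_coverage"]) or np.allclose(
            cap["goods_coverage"], sg["goods_coverage"], atol=0.05)
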