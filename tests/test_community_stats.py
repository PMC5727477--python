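import numpy as np
import pandas as pd
import pytest

from assemblage import community_stats as cs


def dmat_from_points(X):
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    ids = [f"s{i}" for i in range(len(X))]
    return pd.DataFrame(d, index=ids, columns=ids)


class TestCriticalValue:
    def test_two_sided_five_percent(self):
        assert round(cs.normal_critical_value(0.05), 2) == 1.96

    def test_one_sided(self):
        assert cs.normal_critical_value(0.05, two_sided=False) == pytest.approx(
            1.6449, abs=1e-4
        )


class TestLnTransform:
    def test_zero_differences_replaced_by_half_smallest(self, caplog):
        with caplog.at_level("WARNING", logger="assemblage"):
            out = cs.ln_transform_differences(np.array([0.0, 2.0, 4.0]))
        assert out[0] == pytest.approx(np.log(1.0))
        assert "zero differences" in caplog.text

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            cs.ln_transform_differences(np.zeros(3))


class TestMantel:
    def test_identity_gives_r_one_min_p(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 2))
        d = dmat_from_points(X)
        res = cs.mantel_test(d, d.copy(), n_perm=199, rng_seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0 / 200.0)

    def test_anticorrelation_under_greater_tail(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 2))
        d = dmat_from_points(X)
        neg = d.max().max() - d
        np.fill_diagonal(neg.values, 0)
        res = cs.mantel_test(d, neg, n_perm=199, rng_seed=3)
        assert res.r < -0.9
        assert res.p_value > 0.9

    def test_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix, mantel

        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 3))
        Y = X + rng.normal(scale=0.5, size=X.shape)
        d1, d2 = dmat_from_points(X), dmat_from_points(Y)
        mine = cs.mantel_test(d1, d2, n_perm=199, rng_seed=5)
        ref_r, ref_p, _ = mantel(
            DistanceMatrix(d1.values, ids=d1.index),
            DistanceMatrix(d2.values, ids=d2.index),
            method="pearson", permutations=199, alternative="greater",
        )
        assert mine.r == pytest.approx(float(ref_r), abs=1e-12)
        assert mine.p_value < 0.05 and ref_p < 0.05

    def test_constant_matrix_rejected(self):
        ids = list("abc")
        ones = pd.DataFrame(1.0 - np.eye(3), index=ids, columns=ids)
        with pytest.raises(ValueError, match="constant"):
            cs.mantel_test(ones, ones)

    def test_invariant_to_joint_reordering(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(9, 2))
        Y = rng.normal(size=(9, 2))
        d1, d2 = dmat_from_points(X), dmat_from_points(Y)
        perm = list(rng.permutation(d1.index))
        r1 = cs.mantel_test(d1, d2, n_perm=99, rng_seed=7).r
        r2 = cs.mantel_test(
            d1.loc[perm, perm], d2.loc[perm, perm], n_perm=99, rng_seed=7
        ).r
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestMeanDeviationTest:
    def test_all_zeros_p_one(self):
        res = cs.mean_deviation_test(np.zeros(10), n_perm=499, rng_seed=0)
        assert res.mean == 0.0 and res.p_value == 1.0

    def test_extreme_values_minimal_p(self):
        res = cs.mean_deviation_test(np.full(20, 5.0), n_perm=999, rng_seed=1)
        assert res.p_value == pytest.approx(1.0 / 1000.0)

    def test_summary_statistics(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        res = cs.mean_deviation_test(v, n_perm=199, rng_seed=2, group="g")
        assert res.mean == pytest.approx(2.5)
        assert res.sd == pytest.approx(v.std(ddof=1))
        assert res.group == "g" and res.n == 4


class TestPermdisp:
    def test_euclidean_distances_match_direct_geometry(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(16, 4))
        groups = pd.Series(["a"] * 8 + ["b"] * 8,
                           index=[f"s{i}" for i in range(16)])
        d = dmat_from_points(X)
        res = cs.permdisp(d, groups, n_perm=99, rng_seed=4)
        direct = np.empty(16)
        for g, idx in [("a", range(8)), ("b", range(8, 16))]:
            c = X[list(idx)].mean(axis=0)
            for i in idx:
                direct[i] = np.linalg.norm(X[i] - c)
        assert np.allclose(res.distances.values, direct, atol=1e-10)

    def test_translated_clouds_equal_dispersion(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 3))
        Y = X + 100.0  # identical shape, distant location
        d = dmat_from_points(np.vstack([X, Y]))
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=d.index)
        res = cs.permdisp(d, groups, n_perm=199, rng_seed=6)
        assert res.group_means["a"] == pytest.approx(res.group_means["b"], rel=1e-9)
        assert res.p_value > 0.2

    def test_detects_threefold_dispersion_difference(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 3))
        Y = rng.normal(size=(20, 3)) * 3.0
        d = dmat_from_points(np.vstack([X, Y]))
        groups = pd.Series(["a"] * 20 + ["b"] * 20, index=d.index)
        res = cs.permdisp(d, groups, n_perm=499, rng_seed=8)
        assert res.p_value < 0.05

    def test_signed_dissimilarities_shifted(self, caplog):
        rng = np.random.default_rng(9)
        M = rng.normal(size=(8, 8))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        ids = [f"s{i}" for i in range(8)]
        d = pd.DataFrame(D, index=ids, columns=ids)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=ids)
        res = cs.permdisp(d, groups, n_perm=99, rng_seed=10)
        assert res.shifted
        assert np.isfinite(res.f_statistic)

    def test_single_group_rejected(self):
        d = dmat_from_points(np.random.default_rng(11).normal(size=(4, 2)))
        with pytest.raises(ValueError, match="2 groups"):
            cs.permdisp(d, pd.Series(["a"] * 4, index=d.index))

    def test_matches_vegan_betadisper(self, tmp_path):
        """Independent oracle: vegan::betadisper distance-to-centroid on a
        non-Euclidean (Bray-Curtis) dissimilarity matrix."""
        import subprocess

        rng = np.random.default_rng(12)
        X = rng.integers(0, 20, size=(10, 12)).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1
        from assemblage.null_models import bray_curtis

        cm = pd.DataFrame(X, index=[f"s{i}" for i in range(10)],
                          columns=[f"t{i}" for i in range(12)])
        d = bray_curtis(cm)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=d.index)
        res = cs.permdisp(d, groups, n_perm=99, rng_seed=13)

        dpath, gpath, out = tmp_path / "d.tsv", tmp_path / "g.tsv", tmp_path / "o.tsv"
        d.to_csv(dpath, sep="\t")
        groups.rename("g").to_csv(gpath, sep="\t")
        (tmp_path / "bd.R").write_text(f"""
suppressMessages(library(vegan))
d <- as.dist(as.matrix(read.table("{dpath}", sep="\\t", row.names=1, header=TRUE)))
g <- read.table("{gpath}", sep="\\t", row.names=1, header=TRUE)$g
bd <- betadisper(d, g, type="centroid")
write.table(data.frame(dist=bd$distances), "{out}", sep="\\t", quote=FALSE)
""")
        subprocess.run(["Rscript", str(tmp_path / "bd.R")], check=True,
                       capture_output=True)
        ref = pd.read_csv(out, sep="\t", index_col=0)["dist"]
        assert np.allclose(res.distances.values, ref.values, atol=1e-8)


class TestSegmentedFit:
    def test_exact_lines_give_unit_r2(self):
        x = np.concatenate([np.linspace(0, 5, 8), np.linspace(5, 10, 8)])
        y = np.where(x <= 5, 2 * x + 1, -3 * x + 26)
        res = cs.segmented_fit(x, y, breakpoint=5.0, n_boot=99, rng_seed=0)
        assert res.left.r2 == pytest.approx(1.0)
        assert res.right.r2 == pytest.approx(1.0)
        assert res.left.slope == pytest.approx(2.0)
        assert res.right.slope == pytest.approx(-3.0)

    def test_constant_y(self):
        x = np.linspace(0, 10, 12)
        res = cs.segmented_fit(x, np.ones(12), breakpoint=5.0, n_boot=99, rng_seed=1)
        assert res.left.slope == pytest.approx(0.0)
        assert res.left.r2 == pytest.approx(0.0)

    def test_slope_recovery_with_noise(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 10, 40)
        y = 2 * x + rng.normal(scale=0.1, size=40)
        res = cs.segmented_fit(x, y, breakpoint=5.0, n_boot=499, rng_seed=3)
        for seg in (res.left, res.right):
            assert seg.slope_ci[0] <= 2.0 <= seg.slope_ci[1]
            assert seg.slope == pytest.approx(2.0, abs=0.1)

    def test_boundary_point_in_both_segments(self):
        x = np.array([0.0, 1.0, 2.0, 5.0, 7.0, 8.0, 9.0])
        res = cs.segmented_fit(x, x.copy(), breakpoint=5.0, n_boot=99, rng_seed=4)
        assert res.left.n == 4 and res.right.n == 4

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            cs.segmented_fit([0, 1, 5, 6], [1, 2, 3, 4], breakpoint=3.0)
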