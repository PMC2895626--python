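import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats

import setsig as sg
from setsig.set_statistics import (
    compute_set_features,
    set_centroid,
    set_median,
    set_medoid,
    set_pc1,
    set_tstat,
    set_ustat_logp,
    ustat_moments,
)


class TestCentroidMedian:
    def test_two_gene_mean(self):
        assert set_centroid(np.array([[1.0], [3.0]]))[0] == 2.0

    def test_singleton_identity(self):
        row = np.array([[1.0, 5.0, -2.0]])
        assert np.array_equal(set_centroid(row), row[0])
        assert np.array_equal(set_median(row), row[0])

    def test_against_loop_oracle(self, rng):
        sub = rng.normal(size=(5, 4))
        expected = np.array([sum(sub[k, i] for k in range(5)) / 5 for i in range(4)])
        assert np.allclose(set_centroid(sub), expected, atol=1e-12)

    def test_median_robust_to_outlier(self):
        assert set_median(np.array([[1.0], [100.0], [3.0]]))[0] == 3.0

    def test_median_sort_and_pick_oracle(self, rng):
        sub = rng.normal(size=(6, 3))
        for i in range(3):
            col = sorted(sub[:, i])
            expected = (col[2] + col[3]) / 2
            assert set_median(sub)[i] == pytest.approx(expected, abs=1e-12)

    def test_median_equals_centroid_for_two_genes(self, rng):
        sub = rng.normal(size=(2, 7))
        assert np.allclose(set_median(sub), set_centroid(sub), atol=1e-12)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError, match="empty set"):
            set_centroid(np.empty((0, 3)))


class TestMedoid:
    def test_middle_profile_chosen(self):
        sub = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        profile, idx = set_medoid(sub)
        assert idx == 1 and np.array_equal(profile, [1.0, 1.0])

    def test_tie_breaks_to_lowest_index(self):
        sub = np.array([[0.0, 0.0], [2.0, 2.0]])
        profile, idx = set_medoid(sub)
        assert idx == 0 and np.array_equal(profile, [0.0, 0.0])

    def test_matches_exhaustive_scan(self, rng):
        sub = rng.normal(size=(7, 5))
        centroid = sub.mean(axis=0)
        dists = [np.sqrt(((sub[k] - centroid) ** 2).sum()) for k in range(7)]
        _, idx = set_medoid(sub)
        assert idx == int(np.argmin(dists))

    def test_output_is_a_member_row(self, rng):
        sub = rng.normal(size=(6, 4))
        profile, idx = set_medoid(sub)
        assert np.array_equal(profile, sub[idx])

    def test_distance_restricted_to_training_columns(self, rng):
        sub = rng.normal(size=(5, 8))
        _, idx = set_medoid(sub, distance_columns=range(4))
        centroid = sub[:, :4].mean(axis=0)
        dists = ((sub[:, :4] - centroid) ** 2).sum(axis=1)
        assert idx == int(np.argmin(dists))


class TestTStat:
    def test_arithmetic_example(self):
        # values 1,2,3 in one sample: mean 2, sd 1, s=3 → t = 2·√3
        sub = np.array([[1.0], [2.0], [3.0]])
        assert set_tstat(sub)[0] == pytest.approx(2 * np.sqrt(3), abs=1e-12)

    def test_symmetric_values_give_zero(self):
        sub = np.array([[-1.0], [0.0], [1.0]])
        assert set_tstat(sub)[0] == 0.0

    def test_sd_guard_keeps_value_finite(self):
        sub = np.array([[2.0], [2.0], [2.0]])
        t = set_tstat(sub)[0]
        assert np.isfinite(t)
        assert t == pytest.approx(2.0 / (1e-8 / np.sqrt(3)))


class TestUStat:
    def test_top_ranked_members_reach_maximum(self):
        full = np.arange(20.0).reshape(-1, 1)
        members = [17, 18, 19]  # the three largest values
        s, s_not = 3, 17
        ranks = stats.rankdata(full[:, 0])
        u = ranks[members].sum() - s * (s + 1) / 2
        assert u == s * s_not
        assert set_ustat_logp(full, members)[0] > 0  # over-expressed → positive

    def test_bottom_ranked_members_reach_zero(self):
        full = np.arange(20.0).reshape(-1, 1)
        assert set_ustat_logp(full, [0, 1, 2])[0] < 0
        ranks = stats.rankdata(full[:, 0])
        assert ranks[[0, 1, 2]].sum() - 3 * 4 / 2 == 0.0

    def test_moment_formulas(self):
        mu, var = ustat_moments(10, 90)
        assert mu == 450 and var == 7575

    def test_whole_matrix_set_errors(self):
        with pytest.raises(ValueError, match="complement is empty"):
            set_ustat_logp(np.ones((3, 2)), [0, 1, 2])

    def test_normal_p_close_to_permutation_oracle(self, rng):
        # null data: compare the normal-approximation p with a Monte-Carlo
        # permutation p over random member subsets
        p_genes, s, n_draws = 40, 8, 100_000
        full = rng.normal(size=(p_genes, 3))
        members = np.arange(s)
        feat = set_ustat_logp(full, members)
        mu, var = ustat_moments(s, p_genes - s)
        ranks = stats.rankdata(full, axis=0)
        perm_ranks = np.argsort(rng.random((n_draws, p_genes)), axis=1)[:, :s]
        for i in range(3):
            u_obs = ranks[members, i].sum() - s * (s + 1) / 2
            col = np.sort(ranks[:, i])
            u_perm = col[perm_ranks].sum(axis=1) - s * (s + 1) / 2
            p_perm = np.mean(np.abs(u_perm - mu) >= np.abs(u_obs - mu) - 1e-9)
            p_norm = np.exp(-abs(feat[i]))
            if p_perm >= 0.01:  # below that the MC estimate itself is too noisy
                assert p_norm == pytest.approx(p_perm, rel=0.10)


class TestPC1:
    def test_rank_one_matrix_recovers_sample_pattern(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=9)
        sub = np.outer(a, b)
        scores, v1, dropped = set_pc1(sub)
        corr = np.corrcoef(scores, b)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-8)
        assert not dropped

    def test_sign_convention_nonnegative_centroid_correlation(self, rng):
        for _ in range(5):
            sub = rng.normal(size=(4, 10))
            scores, _, _ = set_pc1(sub)
            centroid = set_centroid(sub)
            assert np.corrcoef(scores, centroid)[0, 1] >= -1e-12

    def test_loading_unit_norm(self, rng):
        _, v1, _ = set_pc1(rng.normal(size=(5, 8)))
        assert np.linalg.norm(v1) == pytest.approx(1.0, abs=1e-12)

    def test_variance_explained_matches_eigen_oracle(self, rng):
        sub = rng.normal(size=(8, 6))
        scores, _, _ = set_pc1(sub)
        y = sub.T
        yk = (y - y.mean(axis=0)) / y.std(axis=0, ddof=1)
        eigvals = np.linalg.eigvalsh(np.cov(yk.T, ddof=1))[::-1]
        share_pca = np.var(scores, ddof=1) / np.trace(np.cov(yk.T, ddof=1))
        share_eig = eigvals[0] / eigvals.sum()
        assert share_pca == pytest.approx(share_eig, rel=1e-10)

    def test_zero_variance_gene_dropped(self):
        sub = np.vstack([np.ones(6), np.arange(6.0), np.arange(6.0)[::-1]])
        _, _, dropped = set_pc1(sub)
        assert dropped == [0]


class TestDispatcher:
    def test_raw_is_identity(self, small_data):
        datasets, mapped, _ = small_data
        ds = datasets[0]
        fm = compute_set_features(ds, None, "raw")
        assert np.array_equal(fm.values, ds.values)
        assert fm.set_names == [str(f) for f in ds.feature_ids]

    def test_centroid_rows_match_per_set_recomputation(self, small_data):
        datasets, mapped, _ = small_data
        ds = datasets[0]
        fm = compute_set_features(ds, mapped, "median")
        for j, name in enumerate(fm.set_names):
            members = mapped.mapped_members[mapped.names.index(name)]
            assert np.allclose(fm.values[j], set_median(ds.values[members]),
                               atol=1e-12)

    def test_tstat_size_exclusion_logged(self, small_data):
        datasets, mapped, _ = small_data
        fm = compute_set_features(datasets[0], mapped, "tstat", min_tstat_size=10)
        sizes = mapped.sizes()
        n_small = int((sizes < 10).sum())
        assert len(fm.excluded_sets) == n_small
        assert fm.n_sets == mapped.n_sets - n_small

    def test_unknown_statistic_errors(self, small_data):
        datasets, mapped, _ = small_data
        with pytest.raises(ValueError, match="unknown statistic"):
            compute_set_features(datasets[0], mapped, "zscore")

    def test_disjoint_singleton_sets_equal_gene_rows(self):
        ds = sg.ExpressionDataset(
            name="t", feature_ids=["g1", "g2"], sample_ids=["s1", "s2", "s3"],
            values=np.arange(6.0).reshape(2, 3))
        coll = sg.GeneSetCollection(sets=[sg.GeneSet("A", "C1", ("g1",)),
                                          sg.GeneSet("B", "C1", ("g2",))])
        mapped, _ = sg.map_collection(coll, ds)
        fm = compute_set_features(ds, mapped, "centroid")
        assert np.array_equal(fm.values, ds.values)


class TestInvariants:
    @given(hst.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_gene_order_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        sub = rng.normal(size=(5, 6))
        perm = rng.permutation(5)
        assert np.allclose(set_centroid(sub), set_centroid(sub[perm]), atol=1e-12)
        assert np.allclose(set_median(sub), set_median(sub[perm]), atol=1e-12)
        p1, _ = set_medoid(sub)
        p2, _ = set_medoid(sub[perm])
        # medoid value set unchanged (chosen row may differ only under exact ties)
        assert any(np.allclose(p2, sub[k]) for k in range(5))
        assert np.allclose(np.sort(p1), np.sort(p1))

    def test_variance_reduction_for_independent_genes(self, rng):
        # independent equal-variance genes: var(centroid) ≈ var(gene)/s
        s, n = 25, 4000
        sub = rng.normal(0, 2.0, size=(s, n))
        v = np.var(set_centroid(sub), ddof=1)
        assert v == pytest.approx(4.0 / s, rel=0.15)

    def test_u_statistic_bounds(self, rng):
        full = rng.normal(size=(30, 10))
        members = rng.choice(30, 6, replace=False)
        ranks = stats.rankdata(full, axis=0)
        u = ranks[members].sum(axis=0) - 6 * 7 / 2
        assert (u >= 0).all() and (u <= 6 * 24).all()
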