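"""PAM clustering, silhouette widths, model selection, core filtering,
and consensus clustering, checked against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

import leatsubtype as L


def _dist_from_points(pts, ids=None):
    pts = np.asarray(pts, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    ids = ids or [f"s{i}" for i in range(len(pts))]
    return L.DistanceMatrix(d, pd.Index(ids), "euclidean")


def _brute_force_kmedoids(d, k):
    """Exhaustive search over all medoid subsets (oracle)."""
    n = d.shape[0]
    best_cost, best = np.inf, None
    for medoids in itertools.combinations(range(n), k):
        cost = d[:, list(medoids)].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost, best = cost, medoids
    return best_cost, best


class TestTopVariableGenes:
    def test_keep_all_is_identity(self, toy_matrix):
        m = toy_matrix(np.random.default_rng(0).normal(size=(5, 6)))
        out = L.top_variable_genes(m, 5)
        assert set(out.gene_ids) == set(m.gene_ids)

    def test_selects_by_variance(self, toy_matrix):
        rng = np.random.default_rng(1)
        base = rng.normal(size=6)
        rows = [base * np.sqrt(0.1), base * np.sqrt(5.0), base * np.sqrt(2.0)]
        m = toy_matrix(np.array(rows))
        out = L.top_variable_genes(m, 2)
        assert set(out.gene_ids) == {"G1", "G2"}

    def test_marker_genes_enriched_in_top_1000(self, default_cohort):
        """Planted markers carry the inter-group variance and are strongly
        enriched among the 1000 most variable corrected genes (null rate
        would be 0.2)."""
        top = L.top_variable_genes(default_cohort["corrected"], 1000)
        markers = set(default_cohort["truth"].marker_genes)
        retention = len(markers & set(top.gene_ids)) / len(markers)
        assert retention >= 0.5

    def test_invalid_n(self, toy_matrix):
        m = toy_matrix(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            L.top_variable_genes(m, 0)


class TestPamKmedoids:
    def test_two_clear_clusters(self, points_1d):
        res = L.pam_kmedoids(points_1d, 2)
        assert res.total_cost == pytest.approx(2.0)
        groups = {}
        for s, c in res.assignment.items():
            groups.setdefault(c, set()).add(s)
        assert set(map(frozenset, groups.values())) == {frozenset({"a", "b"}), frozenset({"c", "d"})}

    def test_k_equals_n(self, points_1d):
        res = L.pam_kmedoids(points_1d, 4)
        assert res.total_cost == 0.0
        assert sorted(res.medoids) == ["a", "b", "c", "d"]

    def test_k1_tie_breaks_to_lower_index(self, points_1d):
        # costs for medoids a..d are 22, 20, 20, 22; the tie goes to 'b'
        res = L.pam_kmedoids(points_1d, 1)
        assert res.medoids == ["b"]
        assert res.total_cost == pytest.approx(20.0)

    def test_matches_exhaustive_search(self):
        """PAM equals the brute-force optimum on all random instances with
        n <= 8, k <= 3."""
        rng = np.random.default_rng(42)
        for trial in range(30):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(1, 4))
            pts = rng.normal(size=(n, 2))
            d = _dist_from_points(pts)
            res = L.pam_kmedoids(d, k)
            oracle_cost, _ = _brute_force_kmedoids(d.values, k)
            assert res.total_cost == pytest.approx(oracle_cost, abs=1e-9)

    def test_cost_beats_random_assignment(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(20, 3))
        d = _dist_from_points(pts)
        res = L.pam_kmedoids(d, 3)
        meds = rng.choice(20, 3, replace=False)
        random_cost = d.values[:, meds].min(axis=1).sum()
        assert res.total_cost <= random_cost + 1e-12

    def test_invalid_k(self, points_1d):
        with pytest.raises(ValueError):
            L.pam_kmedoids(points_1d, 5)


class TestSilhouette:
    def test_hand_computed_widths(self, points_1d):
        assignment = pd.Series([1, 1, 2, 2], index=points_1d.sample_ids)
        s = L.silhouette_widths(points_1d, assignment)
        np.testing.assert_allclose(
            s.to_numpy(), [0.904762, 0.894737, 0.894737, 0.904762], atol=1e-5
        )
        assert s.mean() == pytest.approx(0.899749, abs=1e-5)

    def test_singleton_cluster_is_zero(self):
        d = _dist_from_points([0.0, 1.0, 10.0])
        s = L.silhouette_widths(d, pd.Series([1, 1, 2], index=d.sample_ids))
        assert s.iloc[2] == 0.0

    def test_equidistant_sample_is_zero(self):
        d = _dist_from_points([0.0, 2.0, 4.0, 6.0])
        s = L.silhouette_widths(d, pd.Series([1, 1, 2, 2], index=d.sample_ids))
        # middle samples: a == b is impossible here, but scaling invariance
        # and range hold
        assert ((s >= -1) & (s <= 1)).all()
        s_scaled = L.silhouette_widths(
            L.DistanceMatrix(d.values * 7.5, d.sample_ids, d.metric),
            pd.Series([1, 1, 2, 2], index=d.sample_ids),
        )
        np.testing.assert_allclose(s.to_numpy(), s_scaled.to_numpy(), atol=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(15, 4))
        d = _dist_from_points(pts)
        labels = np.array([1] * 5 + [2] * 5 + [3] * 5)
        mine = L.silhouette_widths(d, pd.Series(labels, index=d.sample_ids))
        theirs = silhouette_samples(d.values, labels, metric="precomputed")
        np.testing.assert_allclose(mine.to_numpy(), theirs, atol=1e-12)

    def test_single_cluster_rejected(self, points_1d):
        with pytest.raises(ValueError):
            L.silhouette_widths(points_1d, pd.Series([1, 1, 1, 1], index=points_1d.sample_ids))


class TestSelectK:
    def test_two_separated_groups(self, toy_matrix):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(50, 12)) * 0.1
        x[:25, :6] += 3.0
        m = toy_matrix(x)
        sel = L.select_k_by_silhouette(m, 2, 5, metric="euclidean")
        assert sel.best_k == 2
        assert not sel.no_structure

    def test_planted_k4_recovered(self, default_cohort):
        top = L.scale_genes(L.top_variable_genes(default_cohort["corrected"], 1000))
        sel = L.select_k_by_silhouette(top, 2, 10)
        assert sel.best_k == 4

    def test_k_max_bound(self, toy_matrix):
        m = toy_matrix(np.random.default_rng(0).normal(size=(10, 5)))
        with pytest.raises(ValueError):
            L.select_k_by_silhouette(m, 2, 5)


class TestCoreFiltering:
    def test_all_positive_keeps_everything(self, points_1d):
        res = L.pam_kmedoids(points_1d, 2)
        retained, excluded = L.filter_core_samples(res)
        assert excluded == []
        assert len(retained) == 4

    def test_retained_plus_excluded_partition(self, default_cohort):
        top = L.scale_genes(L.top_variable_genes(default_cohort["corrected"], 1000))
        res = L.pam_kmedoids(L.sample_distances(top, "pearson"), 4)
        retained, excluded = L.filter_core_samples(res)
        assert len(retained) + len(excluded) == top.n_samples
        assert len(retained) == int((res.silhouette >= 0).sum())

    def test_majority_of_outliers_excluded(self):
        """Low-purity outlier samples mostly receive negative silhouette
        while structured samples are retained."""
        pooled_out, pooled_struct = [], []
        for seed in range(3):
            cfg = L.CohortConfig(seed=seed, n_outliers=12)
            expr, _, truth = L.generate_cohort(cfg)
            corr, _ = L.combat_correct(expr)
            top = L.scale_genes(L.top_variable_genes(corr, 1000))
            res = L.pam_kmedoids(L.sample_distances(top, "pearson"), 4)
            sil = res.silhouette
            pooled_out.extend((sil.loc[truth.outlier_samples] < 0).tolist())
            pooled_struct.extend((sil.loc[truth.structured_samples] >= 0).tolist())
        assert np.mean(pooled_out) > 0.5      # majority of outliers excluded
        assert np.mean(pooled_struct) >= 0.9  # structured samples retained

    def test_no_core_samples_is_an_error(self, points_1d):
        res = L.pam_kmedoids(points_1d, 2)
        res.silhouette[:] = -0.5
        with pytest.raises(ValueError, match="no core samples"):
            L.filter_core_samples(res)


class TestConsensus:
    def test_perfectly_separated_entries_binary(self, toy_matrix):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(30, 10)) * 0.05
        x[:15, :5] += 4.0
        m = toy_matrix(x)
        res = L.consensus_cluster(m, 2, 2, reps=20, subsample_frac=0.8,
                                  metric="euclidean", seed=0)
        entries = res.consensus[2].to_numpy()
        assert np.isin(np.round(entries, 8), [0.0, 1.0]).all()

    def test_hand_tallied_consensus(self, toy_matrix):
        """reps = 2, n = 6: the consensus matrix equals a manual tally of
        the two subsampled clusterings (same documented RNG protocol)."""
        rng_data = np.random.default_rng(8)
        x = rng_data.normal(size=(20, 6))
        m = toy_matrix(x)
        seed, frac, reps, k = 123, 0.8, 2, 2
        res = L.consensus_cluster(m, k, k, reps=reps, subsample_frac=frac,
                                  metric="euclidean", seed=seed)
        # manual tally following the documented protocol
        d = L.sample_distances(m, "euclidean")
        rng = np.random.default_rng(seed)
        n, sub_n = 6, int(np.ceil(frac * 6))
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        for _ in range(reps):
            idx = np.sort(rng.choice(n, size=sub_n, replace=False))
            sub = L.DistanceMatrix(d.values[np.ix_(idx, idx)], d.sample_ids[idx], "euclidean")
            labels = L.pam_kmedoids(sub, k).assignment.to_numpy()
            for a in range(sub_n):
                for b in range(sub_n):
                    co_sample[idx[a], idx[b]] += 1
                    if labels[a] == labels[b]:
                        co_cluster[idx[a], idx[b]] += 1
        expected = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(res.consensus[k].to_numpy(), expected, atol=1e-12)

    def test_matrix_symmetric_unit_diagonal(self, default_cohort):
        top = L.scale_genes(L.top_variable_genes(default_cohort["corrected"], 1000))
        res = L.consensus_cluster(top, 4, 4, reps=10, seed=1)
        c = res.consensus[4].to_numpy()
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert ((c >= 0) & (c <= 1)).all()

    def test_planted_subgroups_are_stable(self, default_cohort):
        """Co-clustering frequency is higher within planted subgroups than
        between them; CDFs are monotone and areas lie in [0, 1]."""
        top = L.scale_genes(L.top_variable_genes(default_cohort["corrected"], 1000))
        res = L.consensus_cluster(top, 4, 4, reps=30, seed=2)
        cons = res.consensus[4].to_numpy()
        labels = default_cohort["truth"].subgroup.to_numpy()
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        off = ~np.eye(len(labels), dtype=bool)
        assert cons[same].mean() > cons[~same & off].mean() + 0.2
        for k, cdf in res.cdf.items():
            assert (np.diff(cdf) >= 0).all()
            assert 0.0 <= res.area[k] <= 1.0

    def test_parameter_validation(self, toy_matrix):
        m = toy_matrix(np.random.default_rng(0).normal(size=(10, 8)))
        with pytest.raises(ValueError):
            L.consensus_cluster(m, 2, 3, reps=1)
        with pytest.raises(ValueError):
            L.consensus_cluster(m, 2, 3, reps=5, subsample_frac=1.5)
        with pytest.raises(ValueError):
            L.consensus_cluster(m, 2, 7, reps=5, subsample_frac=0.5)
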