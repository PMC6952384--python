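"""GMT I/O, pre-ranked GSEA with its permutation null, and GSVA, checked
against brute-force oracles on tiny instances."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, mannwhitneyu

import leatsubtype as L
from leatsubtype.enrichment import GeneSetCollection


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def _running_es(order, members, scores, weight):
    """Plain-loop running-sum oracle: signed extreme deviation."""
    members = set(members)
    hits = [g for g in order if g in members]
    total = sum(abs(scores[g]) ** weight for g in hits)
    miss_dec = 1.0 / (len(order) - len(hits))
    running, extreme = 0.0, 0.0
    for g in order:
        if g in members:
            running += (abs(scores[g]) ** weight / total) if total > 0 else 1.0 / len(hits)
        else:
            running -= miss_dec
        if abs(running) > abs(extreme) or (
            abs(running) == abs(extreme) and running > extreme
        ):
            extreme = running  # exact ties report the positive deviation
    return extreme


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        sets = GeneSetCollection({"S1": ["a", "b", "c"], "S2": ["d", "e"]},
                                 {"S1": "first", "S2": "second"})
        path = tmp_path / "x.gmt"
        L.write_gmt(sets, path)
        assert L.read_gmt(path) == sets

    def test_fixture_counts(self, tmp_path):
        path = tmp_path / "two.gmt"
        path.write_text("SETA\tdesc\tg1\tg2\tg3\nSETB\t\tg4\tg5\n")
        sets = L.read_gmt(path)
        assert len(sets) == 2
        assert len(sets.sets["SETA"]) == 3
        assert len(sets.sets["SETB"]) == 2

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("GOOD\tdesc\tg1\nBADLINE\n")
        with pytest.raises(ValueError, match="line 2"):
            L.read_gmt(path)

    def test_min_size_filter(self):
        sets = GeneSetCollection({"small": ["a", "b", "c"], "big": [f"g{i}" for i in range(10)]})
        filtered = sets.filter_to_universe([f"g{i}" for i in range(10)] + ["a", "b", "c"],
                                           min_size=5)
        assert list(filtered.sets) == ["big"]


class TestGseaPreranked:
    def _scores5(self):
        return pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=[f"g{i}" for i in range(1, 6)])

    def test_singleton_top_rank_es_one(self):
        scores = self._scores5()
        sets = GeneSetCollection({"TOP": ["g1"]})
        res = L.gsea_preranked(scores, sets, weight=0.0, n_perm=2000, seed=0, min_size=1)
        assert res.loc["TOP", "es"] == pytest.approx(1.0)
        # exhaustive oracle over the 5 singleton placements: ES values are
        # (1, .75, .5, -.75, -1); only rank 1 attains ES >= 1, and 3 of 5
        # placements are positive, so the sign-stratified permutation p
        # converges to 1/3
        order = list(scores.index)
        oracle = np.array([_running_es(order, [g], scores, 0.0) for g in order])
        assert (oracle >= 1.0 - 1e-12).sum() == 1
        expected = (oracle[oracle >= 0] >= 1.0 - 1e-12).mean()
        assert res.loc["TOP", "pval"] == pytest.approx(expected, abs=0.04)

    def test_es_matches_loop_oracle_for_every_placement(self):
        scores = self._scores5()
        order = list(scores.index)
        for g in order:
            res = L.gsea_preranked(scores, GeneSetCollection({"S": [g]}),
                                   weight=0.0, n_perm=10, seed=0, min_size=1)
            assert res.loc["S", "es"] == pytest.approx(
                _running_es(order, [g], scores, 0.0), abs=1e-12)

    def test_weighted_es_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(size=40), index=[f"g{i}" for i in range(40)])
        members = [f"g{i}" for i in (3, 7, 11, 20, 35)]
        res = L.gsea_preranked(scores, GeneSetCollection({"S": members}),
                               weight=1.0, n_perm=10, seed=0, min_size=1)
        frame = pd.DataFrame({"score": scores, "gene": scores.index}).sort_values(
            ["score", "gene"], ascending=[False, True], kind="mergesort")
        assert res.loc["S", "es"] == pytest.approx(
            _running_es(list(frame.index), members, scores, 1.0), abs=1e-12)

    def test_bottom_set_negative_es(self):
        scores = self._scores5()
        res = L.gsea_preranked(scores, GeneSetCollection({"BOT": ["g4", "g5"]}),
                               weight=0.0, n_perm=100, seed=0, min_size=1)
        assert res.loc["BOT", "es"] < 0
        assert np.sign(res.loc["BOT", "nes"]) == np.sign(res.loc["BOT", "es"])

    def test_monotone_rescaling_invariance_at_weight_zero(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.uniform(1, 10, 30), index=[f"g{i}" for i in range(30)])
        members = [f"g{i}" for i in range(0, 30, 4)]
        sets = GeneSetCollection({"S": members})
        a = L.gsea_preranked(scores, sets, weight=0.0, n_perm=50, seed=3, min_size=1)
        b = L.gsea_preranked(scores ** 3, sets, weight=0.0, n_perm=50, seed=3, min_size=1)
        assert a.loc["S", "es"] == pytest.approx(b.loc["S", "es"], abs=1e-12)
        assert a.loc["S", "pval"] == b.loc["S", "pval"]

    def test_pvalues_in_unit_interval_and_reproducible(self, default_cohort, default_ranking):
        sets = L.generate_gene_sets(default_cohort["truth"], seed=0)
        scores = L.rank_from_classifier(default_ranking, "C2")
        a = L.gsea_preranked(scores, sets, n_perm=200, seed=5)
        b = L.gsea_preranked(scores, sets, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert ((a["pval"] > 0) & (a["pval"] <= 1)).all()
        assert (np.sign(a["nes"]) == np.sign(a["es"])).all()
        for name, members in sets:
            lead = a.loc[name, "leading_edge"]
            assert set(lead) <= set(members)

    def test_planted_sets_enriched_in_own_subgroup(self, default_cohort, default_ranking):
        sets = L.generate_gene_sets(default_cohort["truth"], seed=0)
        for sub in ("C1", "C2"):
            res = L.gsea_preranked(L.rank_from_classifier(default_ranking, sub),
                                   sets, n_perm=500, seed=0)
            assert res.loc[f"PLANTED_{sub}", "qval"] < 0.05

    def test_type_one_calibration_on_null_data(self):
        """On null rankings (pure-noise scores, no planted sets) the nominal
        p-value of a random set is calibrated: rejection fraction at alpha
        within 3 Monte-Carlo SDs.  Each replicate draws an independent
        ranking so the p-values are independent."""
        rng = np.random.default_rng(10)
        reps, alpha, hits = 60, 0.05, 0
        genes = [f"g{i}" for i in range(300)]
        for rep in range(reps):
            scores = pd.Series(rng.normal(size=300), index=genes)
            members = list(rng.choice(genes, size=10, replace=False))
            res = L.gsea_preranked(scores, GeneSetCollection({"S": members}),
                                   n_perm=200, seed=rep, min_size=1)
            hits += res.loc["S", "pval"] < alpha
        frac = hits / reps
        assert abs(frac - alpha) <= 3 * np.sqrt(alpha * (1 - alpha) / reps)

    def test_degenerate_inputs_rejected(self):
        zeros = pd.Series(0.0, index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError, match="degenerate"):
            L.gsea_preranked(zeros, GeneSetCollection({"S": ["g1"]}), min_size=1)
        scores = self._scores5()
        with pytest.raises(ValueError, match="whole universe"):
            L.gsea_preranked(scores, GeneSetCollection({"ALL": list(scores.index)}),
                             n_perm=10, min_size=1)


class TestRankFromClassifier:
    def test_scores_equal_shrunken_contrasts(self, default_ranking):
        scores = L.rank_from_classifier(default_ranking, "C1")
        pd.testing.assert_series_equal(
            scores, default_ranking.shrunken_scores["C1"], check_names=False)

    def test_planted_markers_positive_for_own_subgroup(self, default_cohort, default_ranking):
        truth = default_cohort["truth"]
        scores = L.rank_from_classifier(default_ranking, "C3")
        marker_scores = scores.loc[truth.markers["C3"]]
        assert (marker_scores > 0).mean() > 0.95

    def test_unknown_subgroup(self, default_ranking):
        with pytest.raises(KeyError):
            L.rank_from_classifier(default_ranking, "C9")


class TestGsva:
    def _matrix(self, x, genes=None, samples=None):
        genes = genes or [f"G{i}" for i in range(x.shape[0])]
        samples = samples or [f"S{j}" for j in range(x.shape[1])]
        return L.ExpressionMatrix(pd.DataFrame(np.asarray(x, float), index=genes, columns=samples))

    def test_tiny_case_matches_step_by_step_oracle(self):
        """4 genes x 4 samples, one 2-gene set: scores equal an independent
        recomputation of the kernel-CDF -> rank -> random-walk chain."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=(4, 4))
        m = self._matrix(x)
        sets = GeneSetCollection({"S": ["G0", "G2"]})
        result = L.gsva_scores(m, sets, tau=1.0, min_size=1)

        # oracle: explicit loops
        n_genes, n_samples = x.shape
        sd = x.std(axis=1, ddof=1)
        z = np.zeros_like(x)
        for i in range(n_genes):
            for j in range(n_samples):
                z[i, j] = np.mean([norm.cdf((x[i, j] - x[i, k]) / (sd[i] / 4.0))
                                   for k in range(n_samples)])
        for j in range(n_samples):
            order = sorted(range(n_genes), key=lambda i: (-z[i, j], i))
            rank_pos = {i: r for r, i in enumerate(order)}
            sym = {i: abs(n_genes / 2.0 - (rank_pos[i] + 1)) for i in range(n_genes)}
            hits = {0, 2}
            total = sum(sym[i] for i in hits)
            running, vmax, vmin = 0.0, 0.0, 0.0
            for i in order:
                if i in hits:
                    running += sym[i] / total
                else:
                    running -= 1.0 / (n_genes - len(hits))
                vmax, vmin = max(vmax, running), min(vmin, running)
            expected = vmax + vmin
            assert result.loc["S", m.sample_ids[j]] == pytest.approx(expected, abs=1e-10)

    def test_identical_columns_identical_scores(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(20, 4))
        x = np.column_stack([x, x[:, 1]])  # duplicate a sample
        m = self._matrix(x)
        sets = GeneSetCollection({"S": [f"G{i}" for i in range(0, 10)]})
        res = L.gsva_scores(m, sets, min_size=1)
        assert res.iloc[0, 1] == pytest.approx(res.iloc[0, 4], abs=1e-12)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(15, 6))
        m = self._matrix(x)
        sets = GeneSetCollection({"S": ["G2", "G5", "G9"]})
        a = L.gsva_scores(m, sets, min_size=1)
        perm = rng.permutation(15)
        m2 = m.subset_genes(m.gene_ids[perm])
        b = L.gsva_scores(m2, sets, min_size=1)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_per_gene_constant_shift_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 5))
        m = self._matrix(x)
        sets = GeneSetCollection({"S": ["G1", "G4", "G7"]})
        a = L.gsva_scores(m, sets, min_size=1)
        shifted = x.copy()
        shifted[3] += 100.0
        b = L.gsva_scores(self._matrix(shifted), sets, min_size=1)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_planted_set_scores_higher_in_own_subgroup(self, default_cohort):
        truth = default_cohort["truth"]
        sets = L.generate_gene_sets(truth, seed=0)
        top = L.scale_genes(L.top_variable_genes(default_cohort["corrected"], 1000))
        res = L.gsva_scores(top, sets)
        own = res.loc["PLANTED_C2", (truth.subgroup == "C2").to_numpy()]
        rest = res.loc["PLANTED_C2", (truth.subgroup != "C2").to_numpy()]
        assert mannwhitneyu(own, rest, alternative="greater").pvalue < 0.01

    def test_too_few_samples_rejected(self):
        m = self._matrix(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValueError):
            L.gsva_scores(m, GeneSetCollection({"S": ["G0", "G1"]}), min_size=1)
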