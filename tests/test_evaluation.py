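"""Clustering metrics, PCA/k-means benchmark and gold-standard statistics."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score

import markerselect as ms
from markerselect.matrix import ExpressionMatrixError

from conftest import annotation


class TestPartitionMetrics:
    def test_identical_partitions_up_to_relabeling(self):
        assert ms.nmi(["A", "A", "B", "B"], [1, 1, 2, 2]) == pytest.approx(1.0)
        assert ms.adjusted_rand_index(["A", "A", "B", "B"], [1, 1, 2, 2]) == 1.0
        assert ms.purity([1, 1, 2, 2], ["A", "A", "B", "B"]) == 1.0

    def test_single_cluster_carries_no_information(self):
        assert ms.nmi(["A", "A", "B", "B"], [0, 0, 0, 0]) == 0.0

    def test_independent_partitions(self):
        a, b = ["A", "A", "B", "B"], [1, 2, 1, 2]
        assert ms.nmi(a, b) == pytest.approx(0.0, abs=1e-12)
        # standard pair-count arithmetic gives -1/2 for this pair
        assert ms.adjusted_rand_index(a, b) == pytest.approx(-0.5)

    def test_purity_hand_count(self):
        # clusters {A,A,B} and {B,B} -> (2 + 2) / 5
        pred = [1, 1, 1, 2, 2]
        truth = ["A", "A", "B", "B", "B"]
        assert ms.purity(pred, truth) == pytest.approx(0.8)

    def test_purity_degenerate_singleton_optimum(self):
        assert ms.purity(range(5), ["A", "A", "A", "B", "B"]) == 1.0
        assert ms.purity([0] * 5, ["A", "A", "A", "B", "B"]) == pytest.approx(0.6)

    def test_nmi_and_ari_are_symmetric(self):
        rng = np.random.default_rng(0)
        a, b = rng.integers(0, 3, 40), rng.integers(0, 4, 40)
        assert ms.nmi(a, b) == pytest.approx(ms.nmi(b, a))
        assert ms.adjusted_rand_index(a, b) == pytest.approx(
            ms.adjusted_rand_index(b, a)
        )

    def test_ari_of_random_partitions_is_centered_on_zero(self):
        rng = np.random.default_rng(1)
        vals = [
            ms.adjusted_rand_index(rng.integers(0, 3, 30), rng.integers(0, 3, 30))
            for _ in range(10_000)
        ]
        assert abs(np.mean(vals)) < 0.01

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ExpressionMatrixError):
            ms.nmi([1, 2], [1, 2, 3])


class TestPCAEmbed:
    def _matrix(self, values):
        n, s = values.shape
        return ms.ExpressionMatrix(values, [f"g{i}" for i in range(n)],
                                   [f"s{i}" for i in range(s)])

    def test_rank_one_data_has_no_second_component(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        values = np.vstack([2 * base, 3 * base, 5 * base])
        coords = ms.pca_embed(self._matrix(values))
        assert np.var(coords[:, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_gene_row_order_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.exponential(2, (20, 6))
        m = self._matrix(values)
        shuffled = ms.ExpressionMatrix(
            values[::-1], [f"g{i}" for i in range(19, -1, -1)], m.sample_ids
        )
        np.testing.assert_allclose(
            ms.pca_embed(m), ms.pca_embed(shuffled), atol=1e-8
        )

    def test_component_variances_match_eigendecomposition(self):
        rng = np.random.default_rng(3)
        values = rng.exponential(2, (15, 8))
        coords = ms.pca_embed(self._matrix(values))
        X = values.T - values.T.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        got = np.var(coords, axis=0, ddof=1)
        np.testing.assert_allclose(got, eigvals[:2], rtol=1e-8)
        assert got[0] >= got[1]

    def test_too_few_genes_is_an_error(self):
        with pytest.raises(ExpressionMatrixError, match="two genes"):
            ms.pca_embed(self._matrix(np.ones((1, 4))))


class TestKMeansQuality:
    def test_separable_clouds_score_one_on_all_metrics(self):
        rng = np.random.default_rng(4)
        coords = np.vstack(
            [rng.normal(0, 0.05, (10, 2)), rng.normal(5, 0.05, (10, 2))]
        )
        labels = ["a"] * 10 + ["b"] * 10
        q = ms.kmeans_quality(coords, labels, k=2, runs=20, seed=0)
        assert q.nmi == q.purity == q.ari == 1.0
        assert q.nmi_sd == 0.0

    def test_seeded_reruns_are_identical(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(0, 1, (12, 2))
        labels = ["a", "b", "c"] * 4
        q1 = ms.kmeans_quality(coords, labels, k=3, runs=10, seed=9)
        q2 = ms.kmeans_quality(coords, labels, k=3, runs=10, seed=9)
        assert q1 == q2

    def test_k_larger_than_samples_is_an_error(self):
        with pytest.raises(ExpressionMatrixError):
            ms.kmeans_quality(np.zeros((3, 2)), ["a", "b", "c"], k=4, runs=1, seed=0)

    def test_quality_grows_with_cluster_separation(self):
        qualities = []
        for separation in (0.5, 8.0):
            m, ann, _ = ms.simulate_expression(
                marker_mean=separation, noise_sd=1.0, n_background=100, seed=6
            )
            coords = ms.pca_embed(m)
            labels = ann.labels_for(m.sample_ids)
            qualities.append(
                ms.kmeans_quality(coords, labels, k=ann.t, runs=30, seed=6).nmi
            )
        assert qualities[1] >= qualities[0]


class TestRankedBenchmark:
    def test_perfect_ranking_has_unit_areas(self):
        genes = ["g1", "g2", "g3", "g4"]
        scores = [0.0, 0.1, 0.8, 0.9]
        gold = {"g1", "g2"}
        _, auprc = ms.pr_curve_and_auprc(genes, scores, "low_is_specific", gold)
        _, auroc = ms.roc_auroc(genes, scores, "low_is_specific", gold)
        assert auprc == 1.0 and auroc == 1.0

    def test_interleaved_ranking_hand_summation(self):
        genes = ["g1", "n1", "g2", "n2"]
        scores = [0.9, 0.8, 0.7, 0.6]  # high = specific
        curve, auprc = ms.pr_curve_and_auprc(
            genes, scores, "high_is_specific", {"g1", "g2"}
        )
        np.testing.assert_allclose(curve["precision"], [1, 1 / 2, 2 / 3, 1 / 2])
        assert auprc == pytest.approx((1 + 2 / 3) / 2)

    def test_polarity_flip_inverts_the_ranking(self):
        genes = ["g1", "g2", "n1", "n2"]
        scores = [0.0, 0.1, 0.8, 0.9]
        _, good = ms.pr_curve_and_auprc(genes, scores, "low_is_specific", {"g1", "g2"})
        _, bad = ms.pr_curve_and_auprc(genes, scores, "high_is_specific", {"g1", "g2"})
        assert bad < good == 1.0

    def test_agrees_with_sklearn_average_precision_without_universe(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(60)]
        scores = rng.normal(size=60)
        gold = set(rng.choice(genes, size=12, replace=False))
        _, auprc = ms.pr_curve_and_auprc(genes, scores, "high_is_specific", gold)
        y = [g in gold for g in genes]
        assert auprc == pytest.approx(average_precision_score(y, scores))

    def test_universe_caps_recall_for_unlisted_gold_genes(self):
        universe = ["g1", "g2", "n1", "n2"]
        # detector only ever listed g1; g2 is gold but unreachable
        _, auprc = ms.pr_curve_and_auprc(
            ["g1", "n1"], [0.9, 0.1], "high_is_specific", {"g1", "g2"},
            universe=universe,
        )
        assert auprc == pytest.approx(0.5)

    def test_areas_invariant_under_monotone_score_transforms(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(40)]
        scores = rng.normal(size=40)
        gold = set(rng.choice(genes, size=8, replace=False))
        _, a1 = ms.pr_curve_and_auprc(genes, scores, "high_is_specific", gold)
        _, a2 = ms.pr_curve_and_auprc(
            genes, np.exp(scores), "high_is_specific", gold
        )
        assert a1 == pytest.approx(a2)
        _, r1 = ms.roc_auroc(genes, scores, "high_is_specific", gold)
        _, r2 = ms.roc_auroc(genes, np.exp(scores), "high_is_specific", gold)
        assert r1 == pytest.approx(r2)

    def test_all_tied_scores_give_chance_auroc(self):
        genes = ["g1", "g2", "n1", "n2"]
        _, auroc = ms.roc_auroc(genes, [1, 1, 1, 1], "high_is_specific", {"g1", "g2"})
        assert auroc == 0.5

    def test_empty_gold_set_is_an_error(self):
        with pytest.raises(ExpressionMatrixError):
            ms.pr_curve_and_auprc(["g1"], [0.5], "high_is_specific", set())


class TestOverlapZTest:
    def test_identical_sets_are_extremely_significant(self):
        universe = [f"g{i}" for i in range(1000)]
        gold = set(universe[:10])
        res = ms.overlap_ztest(gold, gold, universe, seed=0)
        assert res.observed == 10
        assert res.p < 1e-6

    def test_p_is_upper_tail_of_z(self):
        from scipy.stats import norm

        universe = [f"g{i}" for i in range(100)]
        predicted = set(universe[:20])
        gold = set(universe[50:70])
        res = ms.overlap_ztest(predicted, gold, universe, n_random=500, seed=3)
        assert res.z == pytest.approx((res.observed - res.random_mean) / res.random_sd)
        assert res.p == pytest.approx(float(norm.sf(res.z)))

    def test_null_pvalues_are_roughly_uniform(self):
        from scipy.stats import kstest

        # large sets so the integer overlap counts approximate a continuum
        universe = [f"g{i}" for i in range(2000)]
        gold = set(universe[:400])
        pvals = []
        for seed in range(200):
            predicted = set(
                np.random.default_rng(1000 + seed).choice(universe, 200,
                                                          replace=False)
            )
            pvals.append(
                ms.overlap_ztest(predicted, gold, universe, n_random=300,
                                 seed=seed).p
            )
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_predicted_outside_universe_is_an_error(self):
        with pytest.raises(ExpressionMatrixError):
            ms.overlap_ztest({"zzz"}, {"g1"}, ["g1", "g2"], seed=0)


class TestEvaluateDetector:
    def test_report_shape_and_gold_rows(self, zero_noise_sim):
        m, ann, truth = zero_noise_sim
        res = ms.detect_markers(m, ann)
        gold = ms.make_gold_standard(truth)
        report = ms.evaluate_detector(m, ann, res, gold=gold, runs=5,
                                      n_random=100, seed=0)
        assert (report["section"] == "clustering").sum() == 1
        gold_rows = report[report["section"] == "gold"]
        assert set(gold_rows["sample_type"]) == set(gold)
        assert (gold_rows["auprc"] == 1.0).all()

    def test_unknown_gold_type_is_an_error(self, zero_noise_sim):
        m, ann, _ = zero_noise_sim
        res = ms.detect_markers(m, ann)
        with pytest.raises(ExpressionMatrixError, match="unknown"):
            ms.evaluate_detector(m, ann, res, gold={"nope": {"M_T1_001"}}, runs=1)

    def test_gold_file_round_trip(self, tmp_path):
        gold = {"T1": {"g1", "g2"}, "T2": {"g3"}}
        ms.write_gold_standard(gold, tmp_path / "gold.tsv")
        assert ms.read_gold_standard(tmp_path / "gold.tsv") == gold
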