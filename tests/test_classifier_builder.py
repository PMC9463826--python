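"""Training-stage contracts: fitting, LOOCV, ROC/AUC, DeLong, stepwise search."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cfpromoter import classifier_builder as cb
from cfpromoter.promoter_coverage import NormalizedMatrix

from conftest import brute_force_auc


def norm_of(X):
    return NormalizedMatrix(
        pd.DataFrame(
            X, index=[f"s{i}" for i in range(len(X))], columns=[f"g{j}" for j in range(X.shape[1])]
        )
    )


@pytest.fixture
def separable():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(20, 3)) * 1e-8
    y = np.array([1] * 10 + [0] * 10)
    X[:, 0] += y * 1e-7  # first gene separates perfectly
    return norm_of(X), y


class TestFitClassifier:
    @pytest.mark.parametrize("model_type", ["svm", "lr"])
    def test_separable_gene_separates_scores(self, separable, model_type):
        norm, y = separable
        spec = cb.fit_classifier(norm, y, ["g0"], model_type)
        s = cb.decision_scores(spec, norm).to_numpy()
        assert s[y == 1].min() > s[y == 0].max()

    @pytest.mark.parametrize("model_type", ["svm", "lr"])
    def test_deterministic(self, separable, model_type):
        norm, y = separable
        a = cb.decision_scores(cb.fit_classifier(norm, y, ["g0", "g1"], model_type, seed=1), norm)
        b = cb.decision_scores(cb.fit_classifier(norm, y, ["g0", "g1"], model_type, seed=1), norm)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 2))
        y = np.array([1] * 15 + [0] * 15)
        X[:, 0] += y * 1.0
        norm = norm_of(X)
        svm_a = cb.decision_scores(cb.fit_classifier(norm, y, ["g0", "g1"], "svm"), norm)
        svm_b = cb.decision_scores(cb.fit_classifier(norm, 1 - y, ["g0", "g1"], "svm"), norm)
        assert np.allclose(svm_a.to_numpy(), -svm_b.to_numpy(), atol=1e-6)
        lr_a = cb.decision_scores(cb.fit_classifier(norm, y, ["g0", "g1"], "lr"), norm)
        lr_b = cb.decision_scores(cb.fit_classifier(norm, 1 - y, ["g0", "g1"], "lr"), norm)
        assert np.allclose(lr_a.to_numpy(), 1.0 - lr_b.to_numpy(), atol=1e-4)

    def test_zero_variance_gene_named(self, separable):
        norm, y = separable
        values = norm.values.copy()
        values["g2"] = 3.14
        with pytest.raises(ValueError, match="g2"):
            cb.fit_classifier(NormalizedMatrix(values), y, ["g0", "g2"], "svm")

    def test_single_class_rejected(self, separable):
        norm, _ = separable
        with pytest.raises(ValueError):
            cb.fit_classifier(norm, np.ones(20, dtype=int), ["g0"], "svm")


class TestLoocv:
    def test_returns_one_score_per_sample(self, separable):
        norm, y = separable
        s = cb.loocv_scores(norm, y, ["g0"], "svm")
        assert len(s) == 20 and list(s.index) == norm.samples

    def test_minimal_balanced_set(self):
        rng = np.random.default_rng(1)
        norm = norm_of(rng.normal(size=(4, 2)))
        s = cb.loocv_scores(norm, np.array([1, 1, 0, 0]), ["g0", "g1"], "lr")
        assert len(s) == 4

    def test_fold_losing_a_class_rejected(self):
        rng = np.random.default_rng(2)
        norm = norm_of(rng.normal(size=(5, 1)))
        with pytest.raises(ValueError, match="class"):
            cb.loocv_scores(norm, np.array([1, 0, 0, 0, 0]), ["g0"], "svm")

    def test_permutation_null_auc_centered(self):
        """Pure-noise features under label permutation: mean LOOCV AUC ~ 0.5."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(24, 4))
        norm = norm_of(X)
        aucs = []
        for _ in range(20):
            y = rng.permutation([1] * 12 + [0] * 12)
            s = cb.loocv_scores(norm, y, list(norm.genes), "lr")
            aucs.append(cb.auc_mann_whitney(s.to_numpy(), y))
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_loocv_prevents_resubstitution_leak(self):
        """On permuted labels resubstitution AUC may soar; LOOCV stays near 0.5."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 10))
        norm = norm_of(X)
        y = rng.permutation([1] * 10 + [0] * 10)
        spec = cb.fit_classifier(norm, y, list(norm.genes), "svm")
        resub = cb.auc_mann_whitney(cb.decision_scores(spec, norm).to_numpy(), y)
        loocv = cb.auc_mann_whitney(
            cb.loocv_scores(norm, y, list(norm.genes), "svm").to_numpy(), y
        )
        assert resub > 0.9  # the leak LOOCV is there to prevent
        assert loocv < resub


class TestRocMetrics:
    def test_perfect_ranking(self):
        rep = cb.roc_metrics([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0], native_threshold=0.75)
        assert rep.auc == 1.0

    def test_pair_counting_value(self):
        rep = cb.roc_metrics([0.9, 0.4, 0.7, 0.1], [1, 1, 0, 0], native_threshold=0.5)
        assert rep.auc == pytest.approx(0.75)

    def test_all_ties_auc_half(self):
        rep = cb.roc_metrics([1.0] * 8, [1, 1, 1, 1, 0, 0, 0, 0], native_threshold=0.5)
        assert rep.auc == pytest.approx(0.5)

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            y = np.zeros(n, dtype=int)
            y[: max(2, n // 3)] = 1
            rng.shuffle(y)
            if y.sum() < 2 or y.sum() > n - 2:
                continue
            scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
            rep = cb.roc_metrics(scores, y, native_threshold=0.0)
            assert rep.auc == pytest.approx(brute_force_auc(scores, y), abs=1e-12)

    def test_confusion_at_native_threshold(self):
        rep = cb.roc_metrics([0.9, 0.3, 0.6, 0.1], [1, 1, 0, 0], native_threshold=0.5)
        assert rep.sensitivity == 0.5 and rep.specificity == 0.5 and rep.accuracy == 0.5

    def test_youden_threshold(self):
        rep = cb.roc_metrics([0.9, 0.8, 0.4, 0.1], [1, 1, 0, 0], threshold_rule="youden")
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            cb.roc_metrics([0.5, 0.6], [1, 1], native_threshold=0.5)


class TestDelong:
    def test_null_interval_covers_half(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=200)
        y = np.array([1] * 100 + [0] * 100)
        lo, hi = cb.auc_confidence_interval(scores, y)
        assert lo <= 0.5 <= hi

    def test_coverage_binormal(self):
        """DeLong intervals cover the true binormal AUC ~95% of the time."""
        rng = np.random.default_rng(9)
        delta = 1.0
        true_auc = stats.norm.cdf(delta / np.sqrt(2))
        n = 40
        y = np.array([1] * n + [0] * n)
        cover = 0
        reps = 300
        for _ in range(reps):
            scores = np.concatenate([rng.normal(delta, 1, n), rng.normal(0, 1, n)])
            lo, hi = cb.auc_confidence_interval(scores, y)
            cover += lo <= true_auc <= hi
        assert 0.91 <= cover / reps <= 0.98

    def test_degenerate_falls_back_to_bootstrap(self):
        scores = np.array([2.0, 3.0, 4.0, -1.0, -2.0, -3.0])
        y = np.array([1, 1, 1, 0, 0, 0])
        lo, hi = cb.auc_confidence_interval(scores, y)
        assert 0.0 <= lo <= hi <= 1.0

    def test_bootstrap_and_delong_overlap(self):
        rng = np.random.default_rng(10)
        scores = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 30)])
        y = np.array([1] * 30 + [0] * 30)
        d_lo, d_hi = cb.auc_confidence_interval(scores, y, method="delong")
        b_lo, b_hi = cb.auc_confidence_interval(scores, y, method="bootstrap", seed=1)
        assert max(d_lo, b_lo) < min(d_hi, b_hi)  # intervals overlap


class TestComparePaired:
    def test_identical_classifiers(self):
        scores = np.array([0.1, 0.9, 0.4, 0.8, 0.2, 0.7])
        y = np.array([0, 1, 0, 1, 0, 1])
        assert cb.compare_auc_paired(scores, scores, y) == 1.0

    def test_null_p_uniformish(self):
        rng = np.random.default_rng(11)
        y = np.array([1] * 30 + [0] * 30)
        ps = []
        for _ in range(200):
            a, b = rng.normal(size=(2, 60))
            ps.append(cb.compare_auc_paired(a, b, y))
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_power_perfect_vs_random(self):
        rng = np.random.default_rng(12)
        y = np.array([1] * 100 + [0] * 100)
        perfect = y + rng.normal(0, 1e-3, 200)
        random_scores = rng.normal(size=200)
        assert cb.compare_auc_paired(perfect, random_scores, y) < 0.01

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            cb.compare_auc_paired([0.1, 0.2], [0.1], [1, 0])


class TestStepwise:
    def test_perfect_gene_selected_then_stop(self, separable):
        norm, y = separable
        genes, trace = cb.stepwise_select(norm, y, ["g1", "g0", "g2"], "svm")
        assert genes[0] == "g0"
        assert trace["loocv_auc"].iloc[0] == 1.0
        assert len(genes) == 1  # no improvement possible beyond AUC 1.0

    def test_max_genes_respected(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(24, 8))
        y = np.array([1] * 12 + [0] * 12)
        X += y[:, None] * 0.8
        norm = norm_of(X)
        genes, _ = cb.stepwise_select(norm, y, list(norm.genes), "lr", max_genes=3)
        assert len(genes) <= 3

    def test_duplicate_candidates_selected_once(self, separable):
        norm, y = separable
        genes, _ = cb.stepwise_select(norm, y, ["g0", "g0", "g1"], "svm", max_genes=3)
        assert len(genes) == len(set(genes))

    def test_trace_monotone_nondecreasing(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(20, 6))
        y = np.array([1] * 10 + [0] * 10)
        X[:, :3] += y[:, None] * 0.7
        norm = norm_of(X)
        _, trace = cb.stepwise_select(norm, y, list(norm.genes), "lr", max_genes=6)
        assert (trace["loocv_auc"].diff().dropna() > 0).all()

    def test_empty_candidates_rejected(self, separable):
        norm, y = separable
        with pytest.raises(ValueError, match="empty"):
            cb.stepwise_select(norm, y, [], "svm")


class TestSelectOptimal:
    def test_max_auc_wins(self):
        rep = lambda auc: cb.PerformanceReport(auc, 0, 1, 0, 0, 0, 0, 5, 5)
        assert cb.select_optimal_classifier({"svm": rep(0.83), "lr": rep(0.78)}) == "svm"
        assert cb.select_optimal_classifier({"svm": rep(0.70), "lr": rep(0.78)}) == "lr"

    def test_single_entry(self):
        rep = cb.PerformanceReport(0.6, 0, 1, 0, 0, 0, 0, 5, 5)
        assert cb.select_optimal_classifier({"lr": rep}) == "lr"

    def test_tie_goes_to_svm(self):
        rep = lambda auc: cb.PerformanceReport(auc, 0, 1, 0, 0, 0, 0, 5, 5)
        assert cb.select_optimal_classifier({"lr": rep(0.8), "svm": rep(0.8)}) == "svm"
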