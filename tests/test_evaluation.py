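"""Metric formulas against brute-force oracles, ROC/PR curves, and the
benchmark grid."""

import numpy as np
import pytest

from ecgcompress.evaluation import (
    confusion_matrix,
    metrics_from_confusion,
    roc_pr_curves,
    run_benchmark,
)
from ecgcompress.preprocessing import SplitConfig
from ecgcompress.synthetic import SyntheticBeatSpec, generate_dataset
from ecgcompress.training import TrainConfig


def brute_force_counts(true, pred, positive):
    """One-vs-rest TP/TN/FP/FN by direct enumeration over label pairs."""
    tp = sum(1 for t, p in zip(true, pred) if t == positive and p == positive)
    tn = sum(1 for t, p in zip(true, pred) if t != positive and p != positive)
    fp = sum(1 for t, p in zip(true, pred) if t != positive and p == positive)
    fn = sum(1 for t, p in zip(true, pred) if t == positive and p != positive)
    return tp, tn, fp, fn


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        labels = ["N", "S", "V", "F"] * 2
        m = confusion_matrix(labels, labels, ["N", "S", "V", "F"])
        np.testing.assert_array_equal(m, 2 * np.eye(4, dtype=int))

    def test_collapsed_predictions_fill_one_column(self):
        true = ["N", "S", "V", "F", "S"]
        m = confusion_matrix(true, ["N"] * 5, ["N", "S", "V", "F"])
        assert m[:, 1:].sum() == 0
        assert m[:, 0].sum() == 5

    def test_total_count_conserved(self):
        rng = np.random.default_rng(0)
        names = ["N", "S", "V", "F"]
        true = rng.choice(names, 137)
        pred = rng.choice(names, 137)
        assert confusion_matrix(true, pred, names).sum() == 137

    def test_unknown_label_named_in_error(self):
        with pytest.raises(ValueError, match="'X'"):
            confusion_matrix(["N", "X"], ["N", "N"], ["N"])


class TestMetrics:
    def test_perfect_confusion_gives_all_ones(self):
        report = metrics_from_confusion(5 * np.eye(4, dtype=int))
        assert report.accuracy == 1.0
        assert report.macro_f1 == 1.0
        assert report.score == 1.0

    def test_hand_evaluated_two_class_case(self):
        report = metrics_from_confusion(np.array([[8, 2], [1, 9]]), ["a", "b"])
        row = report.per_class.loc["a"]
        assert row["precision"] == pytest.approx(8 / 9, abs=1e-12)
        assert row["sensitivity"] == pytest.approx(0.8, abs=1e-12)
        assert row["f1"] == pytest.approx(2 * (8 / 9) * 0.8 / (8 / 9 + 0.8), abs=1e-12)
        assert report.accuracy == pytest.approx(17 / 20)

    def test_score_is_squared_macro_f1(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 20, (4, 4))
        m[0, 0] += 1  # ensure nonzero
        report = metrics_from_confusion(m)
        assert report.score == report.macro_f1**2

    def test_matches_brute_force_counter_on_random_vectors(self):
        rng = np.random.default_rng(2)
        names = ["N", "S", "V", "F"]
        for _ in range(25):
            true = rng.choice(names, 60)
            pred = rng.choice(names, 60)
            m = confusion_matrix(true, pred, names)
            report = metrics_from_confusion(m, names)
            for i, name in enumerate(names):
                tp, tn, fp, fn = brute_force_counts(true, pred, name)
                assert m[i, i] == tp
                assert m[i, :].sum() - m[i, i] == fn
                assert m[:, i].sum() - m[i, i] == fp
                expected_p = tp / (tp + fp) if tp + fp else 0.0
                expected_s = tp / (tp + fn) if tp + fn else 0.0
                assert report.per_class.loc[name, "precision"] == pytest.approx(expected_p, abs=1e-12)
                assert report.per_class.loc[name, "sensitivity"] == pytest.approx(expected_s, abs=1e-12)

    def test_macro_f1_bounded_by_arithmetic_means(self):
        rng = np.random.default_rng(3)
        m = rng.integers(0, 30, (4, 4)) + np.eye(4, dtype=int)
        report = metrics_from_confusion(m)
        arithmetic = (report.per_class["precision"] + report.per_class["sensitivity"]) / 2
        assert (report.per_class["f1"] <= arithmetic + 1e-12).all()

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(np.zeros((3, 3), dtype=int))

    def test_zero_denominators_return_zero(self):
        # class 'b' never predicted and never true
        report = metrics_from_confusion(np.array([[4, 0], [0, 0]]), ["a", "b"])
        assert report.per_class.loc["b", "precision"] == 0.0
        assert report.per_class.loc["b", "sensitivity"] == 0.0


class TestROCPR:
    def test_perfect_separation_has_auc_one(self):
        probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        curves = roc_pr_curves(probs, ["a", "a", "b", "b"], ["a", "b"])
        assert curves["a"]["roc_auc"] == pytest.approx(1.0)
        assert curves["b"]["roc_auc"] == pytest.approx(1.0)

    def test_constant_scores_sit_on_chance_diagonal(self):
        probs = np.full((20, 2), 0.5)
        labels = ["a"] * 10 + ["b"] * 10
        curves = roc_pr_curves(probs, labels, ["a", "b"])
        assert curves["a"]["roc_auc"] == pytest.approx(0.5)

    def test_single_class_truth_skipped(self):
        probs = np.full((4, 2), 0.5)
        curves = roc_pr_curves(probs, ["a"] * 4, ["a", "b"])
        assert curves == {}

    def test_trapezoid_auc_matches_mann_whitney(self):
        """AUC from the ROC trapezoid rule equals the pairwise-comparison
        probability estimator."""
        rng = np.random.default_rng(4)
        labels = np.array(["a"] * 25 + ["b"] * 25)
        scores = np.where(labels == "a", rng.normal(0.6, 0.2, 50), rng.normal(0.4, 0.2, 50))
        probs = np.column_stack([scores, 1 - scores])
        curves = roc_pr_curves(probs, labels, ["a", "b"])
        pos = scores[labels == "a"]
        neg = scores[labels == "b"]
        pairs = [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
        assert curves["a"]["roc_auc"] == pytest.approx(np.mean(pairs), abs=1e-9)

    def test_roc_is_monotone_in_fpr(self):
        rng = np.random.default_rng(5)
        probs = rng.dirichlet(np.ones(2), 40)
        labels = rng.choice(["a", "b"], 40)
        curves = roc_pr_curves(probs, labels, ["a", "b"])
        for c in curves.values():
            assert (np.diff(c["fpr"]) >= 0).all()


class TestBenchmark:
    @pytest.fixture(scope="class")
    def grid(self):
        # 50/class -> 160 training beats, enough rank for PCA at k=130
        dataset = generate_dataset(SyntheticBeatSpec(seed=0), n_per_class=50)
        return run_benchmark(
            dataset,
            crs=(0.5, 0.05),
            methods=("cnn", "pca"),
            train_config=TrainConfig(epochs=2, seed=0),
            split_config=SplitConfig(seed=0),
        )

    def test_shape_and_bounds(self, grid):
        assert grid.accuracy.shape == (2, 2)
        values = grid.accuracy.to_numpy()
        assert ((values >= 0) & (values <= 1)).all()

    def test_seeds_recorded_per_cell(self, grid):
        assert grid.seeds.shape == grid.accuracy.shape
        assert grid.seeds.to_numpy().dtype.kind in "iu"

    def test_deterministic_rerun(self, grid):
        dataset = generate_dataset(SyntheticBeatSpec(seed=0), n_per_class=50)
        again = run_benchmark(
            dataset,
            crs=(0.5, 0.05),
            methods=("cnn", "pca"),
            train_config=TrainConfig(epochs=2, seed=0),
            split_config=SplitConfig(seed=0),
        )
        np.testing.assert_array_equal(grid.accuracy.to_numpy(), again.accuracy.to_numpy())

    def test_infeasible_cell_reported_as_nan_not_fatal(self):
        """A PCA cell whose k exceeds the training-set rank is skipped with
        NaN while the rest of the grid completes."""
        dataset = generate_dataset(SyntheticBeatSpec(seed=0), n_per_class=20)
        result = run_benchmark(
            dataset,
            crs=(0.5, 0.05),
            methods=("pca",),
            train_config=TrainConfig(epochs=1, seed=0),
        )
        assert np.isnan(result.accuracy.loc[0.5, "pca"])  # rank-deficient
        assert np.isfinite(result.accuracy.loc[0.05, "pca"])  # k=13 fits
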