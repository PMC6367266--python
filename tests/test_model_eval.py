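import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from cfrp.feature_selection import SelectionConfig
from cfrp.model_eval import (
    CVConfig,
    MetricsReport,
    compute_metrics,
    confusion_at_threshold,
    featurize_dataset,
    k_fold_cross_validate,
    run_variant,
    train_classifier,
)


def scores_for_confusion(tp, tn, fp, fn):
    """Scores/labels realizing a given confusion at threshold 0.5."""
    y = [1] * tp + [0] * tn + [0] * fp + [1] * fn
    s = [0.9] * tp + [0.1] * tn + [0.9] * fp + [0.1] * fn
    return np.array(s), np.array(y)


class TestComputeMetrics:
    def test_perfect_classifier(self):
        scores, y = scores_for_confusion(50, 50, 0, 0)
        rep = compute_metrics(scores, y)
        for name in ("acc", "sen", "spe", "pre", "mcc", "auc"):
            assert getattr(rep, name) == pytest.approx(1.0)
        assert rep.sum == pytest.approx(6.0)

    def test_uninformative_confusion_gives_zero_mcc(self):
        scores, y = scores_for_confusion(25, 25, 25, 25)
        rep = compute_metrics(scores, y)
        assert rep.mcc == pytest.approx(0.0)
        assert rep.acc == pytest.approx(0.5)

    def test_direct_formula_evaluation(self):
        scores, y = scores_for_confusion(60, 30, 10, 20)
        rep = compute_metrics(scores, y)
        assert rep.pre == pytest.approx(6 / 7)
        assert rep.mcc == pytest.approx(1600 / math.sqrt(70 * 80 * 40 * 50))
        assert rep.acc == pytest.approx(90 / 120)
        assert rep.sen == pytest.approx(60 / 80)
        assert rep.spe == pytest.approx(30 / 40)

    def test_precision_zero_when_no_positive_predictions(self):
        y = np.array([1, 0, 1, 0])
        scores = np.array([0.1, 0.2, 0.3, 0.4])
        rep = compute_metrics(scores, y)
        assert rep.pre == 0.0

    def test_single_class_raises_with_guidance(self):
        with pytest.raises(ValueError, match="AUC"):
            compute_metrics(np.array([0.2, 0.8]), np.array([1, 1]))

    def test_sum_invariant(self, rng):
        for _ in range(20):
            scores = rng.random(30)
            y = rng.integers(0, 2, size=30)
            if len(np.unique(y)) < 2:
                continue
            rep = compute_metrics(scores, y)
            assert rep.sum == pytest.approx(
                rep.acc + rep.sen + rep.spe + rep.pre + rep.mcc + rep.auc, abs=1e-9
            )

    def test_agrees_with_confusion_and_rank_oracles(self, rng):
        """All six metrics vs brute-force counting and sklearn's AUC."""
        for _ in range(100):
            n = int(rng.integers(10, 60))
            scores = rng.random(n)
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            rep = compute_metrics(scores, y)
            tp = sum(1 for s, t in zip(scores, y) if s >= 0.5 and t == 1)
            tn = sum(1 for s, t in zip(scores, y) if s < 0.5 and t == 0)
            fp = sum(1 for s, t in zip(scores, y) if s >= 0.5 and t == 0)
            fn = sum(1 for s, t in zip(scores, y) if s < 0.5 and t == 1)
            assert rep.acc == pytest.approx((tp + tn) / n, abs=1e-9)
            assert rep.sen == pytest.approx(tp / (tp + fn), abs=1e-9)
            assert rep.spe == pytest.approx(tn / (tn + fp), abs=1e-9)
            expected_pre = tp / (tp + fp) if tp + fp else 0.0
            assert rep.pre == pytest.approx(expected_pre, abs=1e-9)
            assert rep.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-9)

    def test_auc_equals_pairwise_comparison_oracle(self, rng):
        scores = rng.random(40)
        y = rng.integers(0, 2, size=40)
        y[0], y[1] = 0, 1
        rep = compute_metrics(scores, y)
        pos = scores[y == 1]
        neg = scores[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert rep.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-9)

    def test_confusion_totals(self):
        scores, y = scores_for_confusion(3, 4, 5, 6)
        c = confusion_at_threshold(scores, y)
        assert (c.tp, c.tn, c.fp, c.fn) == (3, 4, 5, 6)
        assert c.total == 18


def _separable_toy(n=40):
    rng = np.random.default_rng(5)
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    X = rng.normal(size=(n, 2))
    X[:, 0] += y * 8.0  # wide margin
    return pd.DataFrame(X, columns=["f0", "f1"]), y


class TestTrainClassifier:
    @pytest.mark.parametrize("kind", ["rf", "svm", "lr"])
    def test_separable_training_accuracy(self, kind):
        X, y = _separable_toy()
        model = train_classifier(X, y, kind, seed=0)
        pred = (model.predict_scores(X) >= 0.5).astype(int)
        assert (pred == y).mean() == 1.0

    def test_deterministic_given_seed(self):
        X, y = _separable_toy()
        a = train_classifier(X, y, "rf", seed=3).predict_scores(X)
        b = train_classifier(X, y, "rf", seed=3).predict_scores(X)
        np.testing.assert_array_equal(a, b)

    def test_unknown_kind(self):
        X, y = _separable_toy()
        with pytest.raises(ValueError, match="unknown classifier"):
            train_classifier(X, y, "mlp", seed=0)

    def test_single_class_error(self):
        X, _ = _separable_toy()
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(X, np.zeros(len(X), dtype=int), "rf", seed=0)

    def test_scores_in_unit_interval(self):
        X, y = _separable_toy()
        for kind in ("rf", "svm", "lr"):
            s = train_classifier(X, y, kind, seed=0).predict_scores(X)
            assert np.all((s >= 0) & (s <= 1))


class TestCrossValidation:
    def test_partition_contract(self):
        X, y = _separable_toy(100)
        seen = []
        from cfrp.model_eval import _fold_iterator

        for train_idx, test_idx in _fold_iterator(y, CVConfig(n_folds=10, seed=0)):
            assert len(test_idx) == 10
            assert not set(train_idx) & set(test_idx)
            seen.extend(test_idx)
        assert sorted(seen) == list(range(100))

    def test_mean_row_is_fold_average(self):
        X, y = _separable_toy(60)
        rep = k_fold_cross_validate(X, y, CVConfig(n_folds=3, seed=1), "lr")
        assert rep.n_folds == 3
        assert len(rep.per_fold) == 3
        assert rep.auc == pytest.approx(np.mean([f.auc for f in rep.per_fold]))
        assert rep.sum == pytest.approx(
            rep.acc + rep.sen + rep.spe + rep.pre + rep.mcc + rep.auc
        )

    def test_report_frame_shape(self):
        X, y = _separable_toy(60)
        rep = k_fold_cross_validate(X, y, CVConfig(n_folds=3, seed=1), "lr")
        df = rep.to_frame()
        assert list(df.columns) == ["acc", "sen", "spe", "pre", "mcc", "auc", "sum"]
        assert list(df.index) == ["fold1", "fold2", "fold3", "mean"]

    def test_per_fold_selection_runs(self, small_synthetic, kmer22):
        ds, _ = small_synthetic
        X = featurize_dataset(ds, kmer22)
        rep = k_fold_cross_validate(
            X, ds.labels(), CVConfig(n_folds=3, seed=2), "rf",
            SelectionConfig(k=30, forest_trees=50, seed=2, scope="per_fold"),
        )
        assert 0.0 <= rep.auc <= 1.0

    def test_global_scope_selection_runs(self, small_synthetic, kmer22):
        ds, _ = small_synthetic
        X = featurize_dataset(ds, kmer22)
        rep = k_fold_cross_validate(
            X, ds.labels(), CVConfig(n_folds=3, seed=2), "rf",
            SelectionConfig(k=30, forest_trees=50, seed=2, scope="global"),
        )
        assert 0.0 <= rep.auc <= 1.0


class TestRunVariant:
    def test_variant_shapes_and_shared_folds(self, small_synthetic, kmer22):
        ds, _ = small_synthetic
        cv = CVConfig(n_folds=3, seed=7)
        sel = SelectionConfig(k=30, forest_trees=50, seed=7)
        reports = {
            v: run_variant(ds, v, kmer_config=kmer22, selection_config=sel,
                           cv_config=cv)
            for v in ("BaseFeat", "CFRP-raw", "CFRP")
        }
        for rep in reports.values():
            assert isinstance(rep, MetricsReport)
            assert rep.n_folds == 3

    def test_unknown_variant(self, small_synthetic):
        ds, _ = small_synthetic
        with pytest.raises(ValueError, match="unknown variant"):
            run_variant(ds, "CFRP-extra")

    def test_basefeat_width(self, small_synthetic, kmer22):
        ds, _ = small_synthetic
        X = featurize_dataset(ds, kmer22, variant="basefeat")
        assert X.shape == (len(ds.pairs), 16 + 49)

    def test_complex_width(self, small_synthetic, kmer22):
        ds, _ = small_synthetic
        X = featurize_dataset(ds, kmer22, variant="complex")
        assert X.shape == (len(ds.pairs), 4 * 16 * 49)

    def test_basefeat_on_permuted_labels_is_chance(self, kmer22):
        # permuting labels breaks any label-structure coupling, so the
        # concatenated-feature pipeline must score near AUC 0.5
        from cfrp.synthetic_data import SyntheticConfig, simulate_dataset

        ds, _ = simulate_dataset(SyntheticConfig(seed=1))
        X = featurize_dataset(ds, kmer22, variant="basefeat")
        y = np.random.default_rng(1).permutation(ds.labels())
        rep = k_fold_cross_validate(X, y, CVConfig(n_folds=10, seed=1), "rf")
        assert 0.40 <= rep.auc <= 0.60
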