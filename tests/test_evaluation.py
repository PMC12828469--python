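"""Rankings, metric formulas and stratified cross-validation."""

import numpy as np
import pytest

from photorank.evaluation import (
    MetricsReport,
    Ranking,
    cross_validate,
    f1_scores,
    stratified_kfold,
    topk_accuracy,
)


class TestRanking:
    def test_order_is_permutation_sorted_by_probability(self):
        r = Ranking(np.array([0.1, 0.5, 0.2, 0.2]))
        assert sorted(r.order) == [0, 1, 2, 3]
        probs = r.probabilities[r.order]
        assert (np.diff(probs) <= 0).all()

    def test_ties_broken_by_ascending_index(self):
        r = Ranking(np.array([0.25, 0.25, 0.25, 0.25]))
        assert list(r.order) == [0, 1, 2, 3]

    def test_top_k_triples(self):
        r = Ranking(np.array([0.1, 0.6, 0.3]))
        top = r.top_k(2, names=["a", "b", "c"])
        assert top == [(1, "b", 0.6), (2, "c", 0.3)]

    def test_k_out_of_range(self):
        r = Ranking(np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            r.top_k(3)


class TestStratifiedKFold:
    def test_exact_stratification_balanced_two_class(self):
        labels = np.array([0] * 50 + [1] * 50)
        folds = stratified_kfold(labels, k=5, seed=0)
        for f in range(5):
            members = labels[folds == f]
            assert len(members) == 20
            assert (members == 0).sum() == 10 and (members == 1).sum() == 10

    def test_union_is_everything_and_disjoint(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 7, size=213)
        folds = stratified_kfold(labels, k=5, seed=1)
        assert (folds >= 0).all() and (folds < 5).all()
        assert sum((folds == f).sum() for f in range(5)) == len(labels)

    def test_fold_sizes_within_one(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 9, size=157)
        folds = stratified_kfold(labels, k=5, seed=3)
        sizes = [(folds == f).sum() for f in range(5)]
        assert max(sizes) - min(sizes) <= 1

    def test_rare_class_members_in_distinct_folds(self):
        labels = np.array([0] * 40 + [1] * 3)
        with pytest.warns(UserWarning):
            folds = stratified_kfold(labels, k=5, seed=0)
        rare = folds[labels == 1]
        assert len(set(rare)) == 3

    def test_deterministic_given_seed(self):
        labels = np.random.default_rng(4).integers(0, 5, size=100)
        a = stratified_kfold(labels, k=5, seed=9)
        b = stratified_kfold(labels, k=5, seed=9)
        assert np.array_equal(a, b)


class TestF1Scores:
    def test_perfect_predictions(self):
        per, weighted, macro = f1_scores([0, 1, 2], [0, 1, 2], 3)
        assert weighted == macro == 1.0
        assert np.allclose(per, 1.0)

    def test_hand_computed_confusion(self):
        # class0: P=1, R=1/2 -> F=2/3; class1: P=2/3, R=1 -> F=4/5
        per, weighted, macro = f1_scores([0, 0, 1, 1], [0, 1, 1, 1], 2)
        assert np.isclose(per[0], 2 / 3)
        assert np.isclose(per[1], 4 / 5)
        assert np.isclose(macro, 11 / 15)
        assert np.isclose(weighted, 11 / 15)

    def test_never_predicted_rare_class_pulls_macro_below_weighted(self):
        y_true = [0, 0, 0, 0, 1, 1, 1, 2]
        y_pred = [0, 0, 0, 0, 1, 1, 1, 0]
        per, weighted, macro = f1_scores(y_true, y_pred, 3)
        assert per[2] == 0.0
        assert np.isclose(macro, (8 / 9 + 1.0 + 0.0) / 3)
        assert np.isclose(weighted, (4 * 8 / 9 + 3 * 1.0 + 0.0) / 8)
        assert macro < weighted

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            f1_scores([], [], 2)


class TestTopK:
    def test_full_k_is_one(self):
        rng = np.random.default_rng(0)
        proba = rng.dirichlet(np.ones(31), size=40)
        y = rng.integers(0, 31, size=40)
        assert topk_accuracy(proba, y, 31) == 1.0

    def test_k1_equals_plain_accuracy(self):
        rng = np.random.default_rng(1)
        proba = rng.dirichlet(np.ones(5), size=60)
        y = rng.integers(0, 5, size=60)
        acc = (proba.argmax(axis=1) == y).mean()
        assert topk_accuracy(proba, y, 1) == acc

    def test_uniform_random_null_band(self):
        """Random rankings over 31 classes: top-5 hit rate ~ 5/31."""
        rng = np.random.default_rng(2)
        proba = rng.random((10_000, 31))
        proba /= proba.sum(axis=1, keepdims=True)
        y = rng.integers(0, 31, size=10_000)
        p = 5 / 31
        band = 3 * np.sqrt(p * (1 - p) / 10_000)
        assert abs(topk_accuracy(proba, y, 5) - p) < band

    def test_monotone_in_k(self):
        rng = np.random.default_rng(3)
        proba = rng.dirichlet(np.ones(8), size=50)
        y = rng.integers(0, 8, size=50)
        values = [topk_accuracy(proba, y, k) for k in range(1, 9)]
        assert all(a <= b for a, b in zip(values, values[1:]))
        assert values[-1] == 1.0

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            topk_accuracy(np.ones((3, 4)) / 4, [0, 1, 2], 5)


class _ConstantModel:
    """Deterministic dummy: fixed probability row for every input."""

    def __init__(self, row):
        self.row = np.asarray(row)

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        return np.tile(self.row, (len(X), 1))


class TestCrossValidate:
    def test_five_per_fold_entries_and_determinism(self):
        rng = np.random.default_rng(0)
        X = rng.random((100, 8))
        y = rng.integers(0, 2, size=100)
        build = lambda: _ConstantModel([0.6, 0.4])
        a = cross_validate(build, X, y, registry_size=2, k=5, seed=1)
        b = cross_validate(build, X, y, registry_size=2, k=5, seed=1)
        assert len(a.per_fold) == 5
        assert a.to_json() == b.to_json()

    def test_degenerate_identical_folds_have_zero_sd(self):
        # 5 folds x (4+4) identical records; constant model -> identical metrics
        y = np.array([0, 1] * 20)
        X = np.zeros((40, 3))
        report = cross_validate(
            lambda: _ConstantModel([0.7, 0.3]), X, y, registry_size=2, k=5, seed=0
        )
        assert report.sd["accuracy"] == 0.0

    def test_recovery_on_noiseless_synthetic(self, registry, labels_of):
        from photorank.fingerprints import ReactionFeaturizer
        from photorank.mlp import MLPRecommender
        from photorank.synthetic import GeneratorConfig, generate_dataset

        # mild imbalance so every class carries enough records to learn from
        records, _ = generate_dataset(
            GeneratorConfig(
                n_records=600,
                n_templates=31,
                imbalance_exponent=1.0,
                label_noise=0.0,
                seed=21,
                registry=registry,
            )
        )
        y = labels_of(records)
        X = ReactionFeaturizer().fit(records).transform(records)
        report = cross_validate(
            lambda: MLPRecommender(
                registry_size=registry.size, epochs=40, weighted=False, random_state=0
            ),
            X,
            y,
            registry_size=registry.size,
            k=5,
            seed=2,
        )
        assert report.mean["accuracy"] >= 0.95
        assert report.mean["top4"] >= report.mean["top1"]

    def test_report_serializes_to_json(self, tmp_path):
        y = np.array([0, 1] * 10)
        X = np.zeros((20, 2))
        report = cross_validate(
            lambda: _ConstantModel([0.5, 0.5]), X, y, registry_size=2, k=5, seed=0
        )
        path = tmp_path / "report.json"
        report.to_json(path)
        import json

        loaded = json.loads(path.read_text())
        assert len(loaded["per_fold"]) == 5
        assert "accuracy" in loaded["mean"]
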