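"""Model registry, split/train/evaluate, relevance and saturation analyses."""

import numpy as np
import pytest

from nabh.ensemble import (
    ALL_FAMILIES,
    CORE_FAMILIES,
    LabelledDataset,
    ModelSpec,
    TrainedEnsemble,
    _member_seeds,
    cross_validate,
    evaluate,
    feature_relevance,
    feature_saturation,
    metrics_from_confusion,
    split_dataset,
    train_ensemble,
    train_model,
)
from nabh.features import FEATURE_NAMES
from nabh.reference import PUBLISHED_CONFUSION


def toy_dataset(n=40, n_features=2, seed=0, gap=4.0, noise=0.1):
    """Two well-separated Gaussian clusters along the first feature."""
    rng = np.random.default_rng(seed)
    y = np.array([True] * (n // 2) + [False] * (n - n // 2))
    X = rng.normal(0.0, 1.0, size=(n, n_features))
    X[:, 0] = y * gap + rng.normal(0.0, noise, size=n)
    return LabelledDataset(X=X, y=y, ids=[f"s{i}" for i in range(n)])


def signal_matrix(n=240, seed=3, signal_cols=(5,), constant_cols=(), noise=0.3):
    """A 20-feature matrix where only ``signal_cols`` separate the classes."""
    rng = np.random.default_rng(seed)
    y = np.array([True, False] * (n // 2))
    X = rng.normal(0.0, 1.0, size=(n, len(FEATURE_NAMES)))
    for col in signal_cols:
        X[:, col] = y * 2.0 + rng.normal(0.0, noise, size=n)
    for col in constant_cols:
        X[:, col] = 0.37
    return LabelledDataset(X=X, y=y, ids=[f"s{i}" for i in range(n)])


def auc_pairwise(y, scores):
    """Brute-force pairwise-comparison definition of AUC-ROC."""
    pos = scores[y]
    neg = scores[~y]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestSplitDataset:
    def test_benchmark_sizes(self):
        n = 5120
        data = LabelledDataset(
            X=np.zeros((n, 2)),
            y=np.array([True] * 2560 + [False] * 2560),
            ids=[str(i) for i in range(n)],
        )
        train, test = split_dataset(data, 0.3, seed=0)
        assert len(test) == 1536 and len(train) == 3584
        # stratification preserves the class balance exactly here
        assert test.y.sum() == 768

    def test_deterministic_and_disjoint(self, small_data):
        a_train, a_test = split_dataset(small_data, 0.3, seed=11)
        b_train, b_test = split_dataset(small_data, 0.3, seed=11)
        assert a_train.ids == b_train.ids and a_test.ids == b_test.ids
        assert set(a_train.ids).isdisjoint(a_test.ids)
        assert sorted(a_train.ids + a_test.ids) == sorted(small_data.ids)

    def test_four_balanced_items_split_evenly(self):
        data = LabelledDataset(
            X=np.arange(8.0).reshape(4, 2),
            y=np.array([True, True, False, False]),
            ids=list("abcd"),
        )
        train, test = split_dataset(data, 0.5, seed=0)
        assert len(train) == len(test) == 2
        assert train.y.sum() == test.y.sum() == 1

    def test_single_class_is_an_error(self):
        data = LabelledDataset(X=np.zeros((4, 2)), y=np.ones(4, bool), ids=list("abcd"))
        with pytest.raises(ValueError):
            split_dataset(data, 0.3, seed=0)

    def test_bad_fraction_is_an_error(self, small_data):
        with pytest.raises(ValueError):
            split_dataset(small_data, 1.0, seed=0)


class TestTrainModel:
    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_separable_toy_reaches_perfect_training_accuracy(self, family):
        data = toy_dataset()
        model = train_model(ModelSpec(family=family, seed=1), data)
        assert np.mean(model.predict(data.X) == data.y) == 1.0

    def test_fixed_seed_reproduces_winning_hyperparameters(self):
        data = toy_dataset(n=60, seed=5, noise=1.5)
        spec = ModelSpec(family="random_forest", seed=9)
        assert train_model(spec, data).best_params == train_model(spec, data).best_params

    @pytest.mark.parametrize("family", ["logistic_regression", "gradient_boosting"])
    def test_constant_features_predict_majority_class(self, family):
        y = np.array([True] * 30 + [False] * 10)
        data = LabelledDataset(X=np.full((40, 3), 1.5), y=y, ids=[str(i) for i in range(40)])
        model = train_model(ModelSpec(family=family, seed=0), data)
        assert np.mean(model.predict(data.X) == data.y) == pytest.approx(0.75)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(family="rnn")

    def test_single_class_training_is_an_error(self):
        data = LabelledDataset(X=np.zeros((6, 2)), y=np.ones(6, bool), ids=list("abcdef"))
        with pytest.raises(ValueError):
            train_model(ModelSpec(family="svm", seed=0), data)


class TestMetricsFromConfusion:
    @pytest.mark.parametrize(
        "counts,accuracy",
        [
            ((748, 3, 10, 775), 0.9915),  # gradient boosting, published matrix
            ((748, 3, 5, 780), 0.9948),   # ada boost
            ((749, 2, 15, 770), 0.9889),  # svm
        ],
    )
    def test_accuracy_matches_published_reports(self, counts, accuracy):
        assert round(metrics_from_confusion(*counts).accuracy, 4) == accuracy

    def test_weighted_precision_matches_published_report(self):
        report = metrics_from_confusion(*PUBLISHED_CONFUSION["gradient_boosting"])
        assert round(report.precision, 4) == 0.9916

    def test_perfect_classifier(self):
        report = metrics_from_confusion(10, 0, 0, 20)
        assert (report.accuracy, report.precision, report.recall, report.f1) == (1, 1, 1, 1)

    def test_weighted_recall_equals_accuracy_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            TP, FP, FN, TN = rng.integers(0, 500, size=4)
            if TP + FP + FN + TN == 0:
                continue
            report = metrics_from_confusion(int(TP), int(FP), int(FN), int(TN))
            assert report.recall == pytest.approx(report.accuracy)
            for value in (report.accuracy, report.precision, report.recall, report.f1):
                assert 0.0 <= value <= 1.0

    def test_zero_denominator_warns_and_defines_zero(self):
        with pytest.warns(UserWarning, match="denominator"):
            report = metrics_from_confusion(0, 0, 5, 5)
        assert 0.0 <= report.precision <= 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(-1, 0, 0, 1)


class TestEvaluate:
    def test_perfect_on_separable_toy(self):
        train = toy_dataset(seed=0)
        test = toy_dataset(seed=1)
        model = train_model(ModelSpec(family="logistic_regression", seed=0), train)
        report = evaluate(model, test)
        assert report.accuracy == 1.0 and report.auc_roc == 1.0

    def test_auc_equals_pairwise_definition(self):
        train = toy_dataset(n=80, seed=2, gap=1.0, noise=1.0)
        test = toy_dataset(n=120, seed=3, gap=1.0, noise=1.0)
        model = train_model(ModelSpec(family="logistic_regression", seed=0), train)
        report = evaluate(model, test)
        expected = auc_pairwise(test.y, model.decision_scores(test.X))
        assert report.auc_roc == pytest.approx(expected, abs=1e-12)

    def test_label_inversion_flips_auc(self):
        train = toy_dataset(n=80, seed=2, gap=1.0, noise=1.0)
        test = toy_dataset(n=100, seed=4, gap=1.0, noise=1.0)
        model = train_model(ModelSpec(family="svm", seed=0), train)
        inverted = LabelledDataset(X=test.X, y=~test.y, ids=test.ids)
        assert evaluate(model, test).auc_roc + evaluate(model, inverted).auc_roc == pytest.approx(1.0)

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(8)
        n = 400
        y = rng.random(n) < 0.5
        scores = rng.random(n)
        assert auc_pairwise(y, scores) == pytest.approx(0.5, abs=3 / np.sqrt(n))

    def test_single_class_test_is_an_error(self):
        train = toy_dataset()
        model = train_model(ModelSpec(family="logistic_regression", seed=0), train)
        bad = LabelledDataset(X=train.X[:5], y=np.ones(5, bool), ids=train.ids[:5])
        with pytest.raises(ValueError):
            evaluate(model, bad)


class TestCrossValidate:
    def test_separable_toy_is_perfect(self):
        data = toy_dataset(n=60)
        mean, std = cross_validate(ModelSpec("logistic_regression", seed=0), data,
                                   iterations=6, seed=0)
        assert (mean, std) == (1.0, 0.0)

    def test_fifty_iterations_aggregate_fifty_scores(self):
        data = toy_dataset(n=40)
        mean, std, scores = cross_validate(
            ModelSpec("logistic_regression", seed=0), data,
            iterations=50, seed=1, return_scores=True,
        )
        assert len(scores) == 50
        assert mean == pytest.approx(np.mean(scores))

    def test_extending_iterations_reproduces_score_prefix(self):
        data = toy_dataset(n=60, noise=2.0, gap=1.0)
        spec = ModelSpec("knn", seed=0)
        _, _, first = cross_validate(data=data, spec=spec, iterations=4, seed=3,
                                     return_scores=True)
        _, _, longer = cross_validate(data=data, spec=spec, iterations=8, seed=3,
                                      return_scores=True)
        assert longer[:4] == first

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(ModelSpec("knn", seed=0), toy_dataset(), iterations=1)


class TestEnsembleCore:
    def test_member_order_is_fixed(self, small_ensemble):
        assert small_ensemble.families == CORE_FAMILIES
        assert small_ensemble.n_members == 8

    def test_votes_shape(self, small_ensemble, small_split):
        _, test = small_split
        votes = small_ensemble.predict_votes(test.X[:10])
        assert votes.shape == (10, 8) and votes.dtype == bool

    def test_serialization_round_trip(self, small_ensemble, small_split, tmp_path):
        _, test = small_split
        probe = test.X[:50]
        before = small_ensemble.predict_votes(probe)
        small_ensemble.save(tmp_path / "bundle")
        loaded = TrainedEnsemble.load(tmp_path / "bundle")
        assert loaded.families == small_ensemble.families
        assert loaded.seed == small_ensemble.seed
        assert loaded.scales_fingerprint == small_ensemble.scales_fingerprint
        assert np.array_equal(loaded.predict_votes(probe), before)

    def test_manifest_is_plain_text(self, small_ensemble, tmp_path):
        small_ensemble.save(tmp_path / "bundle")
        manifest = (tmp_path / "bundle" / "manifest.txt").read_text()
        assert "families=" in manifest and "feature_order=" in manifest


@pytest.fixture(scope="module")
def signal_ensemble():
    data = signal_matrix(signal_cols=(FEATURE_NAMES.index("freq_basic"),),
                         constant_cols=(FEATURE_NAMES.index("freq_strong_helix_breaker"),))
    return data, train_ensemble(data, seed=2, families=("logistic_regression", "random_forest"))


class TestFeatureRelevance:
    def test_percentages_sum_to_one_hundred(self, signal_ensemble):
        data, ensemble = signal_ensemble
        table = feature_relevance(ensemble, data, seed=0)
        assert sum(table.percentages.values()) == pytest.approx(100.0, abs=0.05)

    def test_constant_feature_has_zero_relevance(self, signal_ensemble):
        data, ensemble = signal_ensemble
        table = feature_relevance(ensemble, data, seed=0)
        assert table.percentages["freq_strong_helix_breaker"] == 0.0

    def test_sole_discriminative_feature_dominates(self, signal_ensemble):
        data, ensemble = signal_ensemble
        table = feature_relevance(ensemble, data, seed=0)
        assert table.ranking()[0] == "freq_basic"


SATURATION_FAMILIES = ("logistic_regression", "gradient_boosting")


@pytest.fixture(scope="module")
def saturation():
    signal = [FEATURE_NAMES.index(n) for n in FEATURE_NAMES[-3:]]
    data = signal_matrix(n=300, seed=6, signal_cols=tuple(signal))
    # ranking puts the three informative features last, so k=3 is blind
    ranking = list(FEATURE_NAMES)
    points = feature_saturation(
        data, k_range=[3, 20], seed=4, families=SATURATION_FAMILIES, ranking=ranking
    )
    return data, points


class TestFeatureSaturation:
    FAMILIES = SATURATION_FAMILIES

    def test_output_size(self, saturation):
        _, points = saturation
        assert len(points) == 2 * len(self.FAMILIES)

    def test_uninformative_top_k_scores_near_chance(self, saturation):
        _, points = saturation
        for p in points:
            if p.k == 3:
                assert p.accuracy < 0.7

    def test_full_feature_set_recovers_signal(self, saturation):
        _, points = saturation
        for p in points:
            if p.k == 20:
                assert p.accuracy > 0.9

    def test_k20_equals_direct_full_feature_run(self, saturation):
        data, points = saturation
        train, test = split_dataset(data, 0.3, seed=4)
        seeds = _member_seeds(4, len(self.FAMILIES))
        for family, seed in zip(self.FAMILIES, seeds):
            model = train_model(ModelSpec(family=family, seed=seed), train)
            direct = float(np.mean(model.predict(test.X) == test.y))
            (point,) = [p for p in points if p.k == 20 and p.family == family]
            assert point.accuracy == direct

    def test_out_of_range_k_rejected(self, saturation):
        data, _ = saturation
        with pytest.raises(ValueError):
            feature_saturation(data, k_range=[0], seed=0, families=self.FAMILIES,
                               ranking=list(FEATURE_NAMES))
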