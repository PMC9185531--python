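"""Dataset splitting, augmentation, and classifier training contracts."""

import numpy as np
import pytest

from glucowave.learn import (
    ConcentrationClassifier,
    DatasetSplit,
    HyperparameterBounds,
    HyperparameterVector,
    augment_white_noise,
    build_network,
    evaluate,
    labels_from_concentrations,
    split_dataset,
)


class TestSplit:
    def test_campaign_split_sizes(self):
        s = split_dataset(1000)
        assert (len(s.train), len(s.validation), len(s.test)) == (850, 100, 50)

    def test_small_n_rounding(self):
        s = split_dataset(20)
        assert (len(s.train), len(s.validation), len(s.test)) == (17, 2, 1)

    def test_deterministic_given_seed(self):
        a = split_dataset(100, seed=5)
        b = split_dataset(100, seed=5)
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.test, b.test)

    def test_disjoint_and_covering(self):
        s = split_dataset(137, seed=3)
        union = np.sort(np.concatenate([s.train, s.validation, s.test]))
        np.testing.assert_array_equal(union, np.arange(137))

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(100, ratios=(0.8, 0.1, 0.2))

    def test_overlapping_lists_rejected(self):
        with pytest.raises(ValueError):
            DatasetSplit(
                train=np.array([0, 1]),
                validation=np.array([1, 2]),
                test=np.array([3]),
            )


class TestAugmentation:
    def test_zero_copies_identity(self, rng):
        x = rng.standard_normal((10, 4, 4, 4))
        y = np.arange(10) % 5
        xa, ya = augment_white_noise(x, y, copies=0)
        assert xa is x and ya is y

    def test_size_arithmetic(self, rng):
        x = rng.standard_normal((850, 2, 2, 4))
        y = np.arange(850) % 5
        xa, ya = augment_white_noise(x, y, copies=3, seed=0)
        assert len(xa) == 3400 and len(ya) == 3400
        np.testing.assert_array_equal(xa[:850], x)
        np.testing.assert_array_equal(ya[:850], y)

    def test_zero_sigma_copies_are_identical(self, rng):
        x = rng.standard_normal((5, 2, 2, 4))
        y = np.arange(5)
        xa, _ = augment_white_noise(x, y, copies=2, sigma=0.0)
        np.testing.assert_array_equal(xa[5:10], x)

    def test_negative_inputs_rejected(self, rng):
        x = rng.standard_normal((5, 2, 2, 4))
        with pytest.raises(ValueError):
            augment_white_noise(x, np.arange(5), copies=-1)
        with pytest.raises(ValueError):
            augment_white_noise(x, np.arange(5), copies=1, sigma=-0.5)


class TestLabels:
    def test_known_classes_map_to_indices(self):
        out = labels_from_concentrations([0.91, 0.69, 1.08])
        np.testing.assert_array_equal(out, [2, 0, 4])

    def test_unknown_concentration_rejected(self):
        with pytest.raises(ValueError, match="not one of the known classes"):
            labels_from_concentrations([0.95])


class TestHyperparameters:
    def test_bounds_validation(self):
        bounds = HyperparameterBounds()
        with pytest.raises(ValueError):
            HyperparameterVector(conv_kernel_size=4).validate(bounds)
        with pytest.raises(ValueError):
            HyperparameterVector(lstm_hidden_size=200).validate(bounds)
        HyperparameterVector(5, 1, 32).validate(bounds)

    def test_build_network_rejects_out_of_bounds(self):
        with pytest.raises(ValueError):
            build_network(HyperparameterVector(9, 1, 16))


def _toy_separable(n_per_class=20, n_classes=2, size=16, seed=0):
    """Two well-separated classes of small tensors."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for c in range(n_classes):
        base = np.zeros((size, size, 4))
        base[:, :, c % 4] = 2.0 * (c + 1)
        for _ in range(n_per_class):
            xs.append(base + 0.1 * rng.standard_normal(base.shape))
            ys.append(c)
    return np.array(xs), np.array(ys)


class TestTraining:
    def test_separable_toy_reaches_full_accuracy(self):
        x, y = _toy_separable()
        split = split_dataset(len(y), ratios=(0.6, 0.3, 0.1), seed=0)
        model = ConcentrationClassifier(
            x, y, split=split,
            hyperparameters=HyperparameterVector(3, 2, 8),
            epochs=15, n_classes=2,
        )
        results = model.fit(seed=0)
        assert max(results.curve.epoch_val_accuracy) == 1.0

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        x, y = _toy_separable(n_per_class=10)
        split = split_dataset(len(y), ratios=(0.6, 0.3, 0.1), seed=0)
        model = ConcentrationClassifier(
            x, y, split=split, epochs=1, lr=0.0, n_classes=2,
            hyperparameters=HyperparameterVector(3, 2, 8),
        )
        before = [p.value.copy() for p in build_network(
            HyperparameterVector(3, 2, 8), seed=0, n_classes=2
        ).parameters()]
        results = model.fit(seed=0)
        for p, b in zip(results.network.parameters(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_same_seed_reproduces_training_curve(self):
        x, y = _toy_separable(n_per_class=12)
        split = split_dataset(len(y), ratios=(0.6, 0.3, 0.1), seed=0)
        kwargs = dict(
            split=split, epochs=3, n_classes=2,
            hyperparameters=HyperparameterVector(3, 2, 8),
        )
        r1 = ConcentrationClassifier(x, y, **kwargs).fit(seed=5)
        r2 = ConcentrationClassifier(x, y, **kwargs).fit(seed=5)
        assert r1.curve.epoch_losses == r2.curve.epoch_losses
        assert r1.curve.epoch_val_accuracy == r2.curve.epoch_val_accuracy

    def test_summary_reports_configuration(self):
        x, y = _toy_separable(n_per_class=12)
        split = split_dataset(len(y), ratios=(0.6, 0.3, 0.1), seed=0)
        r = ConcentrationClassifier(
            x, y, split=split, epochs=2, n_classes=2,
            hyperparameters=HyperparameterVector(3, 2, 8),
        ).fit(seed=0)
        assert "bi-LSTM" in r.summary()
        assert "validation accuracy" in r.summary()


class TestEvaluate:
    def test_perfect_predictor(self, rng):
        # a network evaluated against its own argmax predictions
        net = build_network(HyperparameterVector(3, 2, 8), seed=0)
        x = rng.standard_normal((12, 16, 16, 4))
        y = net.predict(x)
        assert evaluate(net, x, y) == 1.0

    def test_uniform_random_predictor_near_chance(self, rng):
        # binomial expectation: 5 balanced classes -> 0.2 +/- 0.05
        labels = rng.integers(0, 5, size=1000)
        preds = rng.integers(0, 5, size=1000)
        acc = float(np.mean(labels == preds))
        assert acc == pytest.approx(0.2, abs=0.05)

    def test_order_invariance(self, rng):
        net = build_network(HyperparameterVector(3, 2, 8), seed=0)
        x = rng.standard_normal((10, 16, 16, 4))
        y = net.predict(x)
        perm = rng.permutation(10)
        assert evaluate(net, x[perm], y[perm]) == evaluate(net, x, y)

    def test_empty_set_rejected(self):
        net = build_network(HyperparameterVector(3, 2, 8), seed=0)
        with pytest.raises(ValueError):
            evaluate(net, np.empty((0, 16, 16, 4)), np.empty(0, dtype=int))
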