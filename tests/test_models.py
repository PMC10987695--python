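"""Classifier designs: probabilistic contract, determinism, learning sanity,
and the Gaussian-process hyperparameter search."""

import numpy as np
import pytest
from sklearn.model_selection import train_test_split

import segvoice as sv
from segvoice.models import (
    Dataset,
    HyperparameterSpace,
    ModelConfig,
    build_model,
    gp_maximize,
    train,
    tune,
)

SMALL_IMG = (24, 32, 3)


def _split(X, y, seed=0, test_size=0.2):
    tr, va = train_test_split(np.arange(len(y)), test_size=test_size,
                              stratify=y, random_state=seed)
    return tr, va


def _toy_images(y, seed=0):
    """Images whose mean brightness encodes the class (learnable signal)."""
    rng = np.random.default_rng(seed)
    imgs = rng.integers(0, 60, size=(len(y),) + SMALL_IMG)
    imgs += (y[:, None, None, None] * 30)
    return np.clip(imgs, 0, 255).astype(np.uint8)


class TestContracts:
    def test_probabilities_sum_to_one(self, battery_small):
        X, y = battery_small
        cfg = ModelConfig(design="dnn", n_features=X.shape[1], seed=0)
        model = build_model(cfg)
        tr, va = _split(X, y)
        train(model, Dataset(labels=y[tr], features=X[tr]), Dataset(labels=y[va], features=X[va]))
        proba = model.predict_proba(features=X)
        assert proba.shape == (60, 6)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(proba >= 0)

    def test_seeded_init_identical(self):
        cfg = ModelConfig(design="dnn", n_features=100, seed=4)
        a, b = build_model(cfg), build_model(cfg)
        for pa, pb in zip(a.net.params, b.net.params):
            np.testing.assert_array_equal(pa, pb)

    def test_cnn_full_size_forward(self):
        cfg = ModelConfig(design="cnn", image_shape=(240, 320, 3), seed=0)
        model = build_model(cfg)
        rng = np.random.default_rng(0)
        imgs = rng.integers(0, 256, (2, 240, 320, 3), dtype=np.uint8)
        proba = model.predict_proba(images=imgs)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_cdnn_requires_both_inputs(self):
        with pytest.raises(ValueError, match="image_shape"):
            build_model(ModelConfig(design="cdnn", n_features=100))
        with pytest.raises(ValueError, match="n_features"):
            build_model(ModelConfig(design="cdnn", image_shape=SMALL_IMG))
        cfg = ModelConfig(design="cdnn", n_features=10, image_shape=SMALL_IMG, seed=0)
        model = build_model(cfg)
        with pytest.raises(ValueError, match="feature"):
            model.predict_proba(images=np.zeros((1,) + SMALL_IMG, dtype=np.uint8))

    def test_inference_deterministic(self, battery_small):
        X, y = battery_small
        cfg = ModelConfig(design="dnn", n_features=X.shape[1], seed=0, dropout=0.5)
        model = build_model(cfg)
        tr, va = _split(X, y)
        train(model, Dataset(labels=y[tr], features=X[tr]), Dataset(labels=y[va], features=X[va]))
        p1 = model.predict_proba(features=X[:5])
        p2 = model.predict_proba(features=X[:5])
        np.testing.assert_array_equal(p1, p2)  # dropout is inference-inert


class TestTraining:
    def test_dnn_beats_chance_on_separated_data(self, battery_small):
        X, y = battery_small
        cfg = ModelConfig(design="dnn", n_features=X.shape[1], seed=0)
        model = build_model(cfg)
        tr, va = _split(X, y)
        train(model, Dataset(labels=y[tr], features=X[tr]), Dataset(labels=y[va], features=X[va]))
        assert max(h["val_bac"] for h in model.history) > 1 / 3  # chance is 1/6

    def test_identical_seeds_give_identical_traces(self, battery_small):
        X, y = battery_small
        cfg = ModelConfig(design="dnn", n_features=X.shape[1], seed=1)
        tr, va = _split(X, y)
        traces = []
        for _ in range(2):
            model = build_model(cfg)
            train(model, Dataset(labels=y[tr], features=X[tr]),
                  Dataset(labels=y[va], features=X[va]))
            traces.append([h["val_accuracy"] for h in model.history])
        assert traces[0] == traces[1]

    def test_max_epochs_respected(self, battery_small):
        X, y = battery_small
        cfg = ModelConfig(design="dnn", n_features=X.shape[1], seed=0, max_epochs=2)
        model = build_model(cfg)
        tr, va = _split(X, y)
        train(model, Dataset(labels=y[tr], features=X[tr]), Dataset(labels=y[va], features=X[va]))
        assert len(model.history) == 2

    def test_empty_partition_rejected(self, battery_small):
        X, y = battery_small
        cfg = ModelConfig(design="dnn", n_features=X.shape[1], seed=0)
        model = build_model(cfg)
        with pytest.raises(ValueError, match="non-empty"):
            train(model, Dataset(labels=y, features=X), Dataset(labels=y[:0], features=X[:0]))

    def test_shuffled_labels_stay_at_chance(self, battery_small):
        """With labels permuted there is nothing to learn: the validation
        BAC posterior must sit within 3 SDs of 1/6."""
        from segvoice.evaluation import BetaPosterior, beta_map, beta_update

        X, y = battery_small
        rng = np.random.default_rng(0)
        y_shuf = rng.permutation(y)
        cfg = ModelConfig(design="dnn", n_features=X.shape[1], seed=0)
        model = build_model(cfg)
        tr, va = _split(X, y_shuf, test_size=0.4)
        train(model, Dataset(labels=y_shuf[tr], features=X[tr]),
              Dataset(labels=y_shuf[va], features=X[va]))
        pred = model.predict(features=X[va])
        correct = int(np.sum(pred == y_shuf[va]))
        post = beta_update(BetaPosterior(), correct, len(va) - correct)
        assert abs(beta_map(post) - 1 / 6) < 3 * post.sd

    def test_cdnn_learns_from_joint_signal(self, battery_small):
        X, y = battery_small
        imgs = _toy_images(y)
        cfg = ModelConfig(design="cdnn", n_features=X.shape[1], image_shape=SMALL_IMG,
                          seed=0, hidden=(32,), conv_filters=(8, 16))
        model = build_model(cfg)
        tr, va = _split(X, y)
        train(model, Dataset(labels=y[tr], features=X[tr], images=imgs[tr]),
              Dataset(labels=y[va], features=X[va], images=imgs[va]))
        assert max(h["val_bac"] for h in model.history) > 1 / 3

    def test_cnn_learns_brightness_classes(self):
        y = np.repeat(np.arange(6), 10)
        imgs = _toy_images(y, seed=1)
        cfg = ModelConfig(design="cnn", image_shape=SMALL_IMG, seed=0,
                          conv_filters=(8, 16), learning_rate=3e-3, max_epochs=4)
        model = build_model(cfg)
        tr, va = _split(None, y, seed=1)
        train(model, Dataset(labels=y[tr], images=imgs[tr]),
              Dataset(labels=y[va], images=imgs[va]))
        assert max(h["val_bac"] for h in model.history) > 1 / 3


class TestTuning:
    def test_gp_beats_noise_on_smooth_function(self):
        """On a smooth 1-D objective the GP search must land within 5% of
        the optimum found by a dense grid."""
        objective = lambda z: float(np.sin(3 * z[0]) * np.exp(-z[0]))  # noqa: E731
        grid = np.linspace(0, 1, 2001)
        truth = grid[np.argmax([objective([g]) for g in grid])]
        z_best, _ = gp_maximize(objective, dim=1, budget=25, seed=0)
        assert abs(z_best[0] - truth) < 0.05

    def test_budget_below_five_rejected(self):
        with pytest.raises(ValueError, match="budget"):
            gp_maximize(lambda z: 0.0, dim=1, budget=4, seed=0)

    def test_tune_returns_config_inside_space(self, battery_small):
        X, y = battery_small
        space = HyperparameterSpace(budget=5)
        cfg = tune(space, Dataset(labels=y, features=X), "dnn", seed=0, tune_epochs=1)
        assert cfg.hidden[0] in space.discrete["width"]
        assert len(cfg.hidden) in space.discrete["depth"]
        assert cfg.batch_size in space.discrete["batch_size"]
        lo, hi, _ = space.continuous["learning_rate"]
        assert lo <= cfg.learning_rate <= hi
        assert 0.0 <= cfg.dropout <= 0.5

    def test_tune_deterministic(self, battery_small):
        X, y = battery_small
        space = HyperparameterSpace(budget=5)
        data = Dataset(labels=y, features=X)
        a = tune(space, data, "dnn", seed=3, tune_epochs=1)
        b = tune(space, data, "dnn", seed=3, tune_epochs=1)
        assert a == b
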