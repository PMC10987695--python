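"""The three classifier designs and their tuning/training machinery.

* **dnn** — a feedforward stack over the 14,244-entry feature vector;
* **cnn** — convolution + 2x2 max-pooling stages over the 240x320x3
  spectrogram image, flattened into a softmax head;
* **cdnn** — both branches run in parallel and their outputs concatenate
  into a shared feedforward head.

All three expose the same probabilistic contract: `predict_proba` returns
six non-negative class probabilities summing to one, and the argmax (ties
to the lowest class index) is the predicted label.  Training runs at most
`max_epochs` epochs (default 4) with the validation split scored after
every epoch; the weights of the best-validation epoch are kept, which is
how overfitting is held in check under such a short budget.

Hyperparameters are found by sequential model-based optimization: a
Gaussian-process surrogate fit to (configuration -> validation score)
observations proposes the next configuration by expected improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.model_selection import train_test_split
from scipy.stats import norm

from . import nn
from .labels import N_CLASSES

DESIGNS = ("dnn", "cnn", "cdnn")


@dataclass
class Dataset:
    """In-memory training data: feature matrix and/or image stack + labels."""

    labels: np.ndarray
    features: np.ndarray | None = None
    images: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = self.labels.size
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=np.float64)
            if self.features.shape[0] != n:
                raise ValueError("features/labels length mismatch")
        if self.images is not None:
            self.images = np.asarray(self.images)
            if self.images.shape[0] != n:
                raise ValueError("images/labels length mismatch")
        if self.features is None and self.images is None:
            raise ValueError("dataset needs features, images, or both")

    def __len__(self) -> int:
        return self.labels.size

    def subset(self, idx) -> "Dataset":
        return Dataset(
            labels=self.labels[idx],
            features=None if self.features is None else self.features[idx],
            images=None if self.images is None else self.images[idx],
        )

    def concat(self, other: "Dataset") -> "Dataset":
        cat = lambda a, b: None if a is None else np.concatenate([a, b])  # noqa: E731
        return Dataset(
            labels=np.concatenate([self.labels, other.labels]),
            features=cat(self.features, other.features),
            images=cat(self.images, other.images),
        )


@dataclass(frozen=True)
class ModelConfig:
    """Architecture + optimization settings for one classifier."""

    design: str = "dnn"
    hidden: tuple[int, ...] = (128, 64)
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 4
    seed: int = 0
    n_features: int | None = None
    image_shape: tuple[int, int, int] | None = None
    conv_filters: tuple[int, ...] = (16, 32, 64)

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}, got {self.design!r}")
        if len(self.hidden) < 1:
            raise ValueError("at least one hidden layer is required")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("learning_rate, batch_size and max_epochs must be positive")


class TrainedModel:
    """A (possibly still untrained) classifier with a uniform predict contract."""

    def __init__(self, config: ModelConfig) -> None:
        if config.design in ("dnn", "cdnn") and config.n_features is None:
            raise ValueError(f"{config.design} requires n_features")
        if config.design in ("cnn", "cdnn") and config.image_shape is None:
            raise ValueError(f"{config.design} requires image_shape")
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.net = self._build(config, self.rng)
        self.optimizer = nn.Adam(self.net.params, lr=config.learning_rate)
        self.scaler_mean: np.ndarray | None = None
        self.scaler_std: np.ndarray | None = None
        self.history: list[dict] = []
        self.epochs_trained = 0

    # --- architecture -------------------------------------------------------

    @staticmethod
    def _dense_stack(n_in: int, hidden: tuple[int, ...], dropout: float,
                     rng: np.random.Generator, out_dim: int | None) -> nn.Sequential:
        layers: list[nn.Layer] = []
        prev = n_in
        for width in hidden:
            layers += [nn.Dense(prev, width, rng), nn.ReLU(), nn.Dropout(dropout, rng)]
            prev = width
        if out_dim is not None:
            layers.append(nn.Dense(prev, out_dim, rng))
        return nn.Sequential(layers)

    @staticmethod
    def _conv_stack(shape: tuple[int, int, int], filters: tuple[int, ...],
                    rng: np.random.Generator, out_dim: int | None) -> nn.Sequential:
        h, w, c = shape
        layers: list[nn.Layer] = []
        prev = c
        for f in filters:
            layers += [nn.Conv2D(prev, f, rng), nn.ReLU(), nn.MaxPool2()]
            prev = f
            h, w = h // 2, w // 2
        layers.append(nn.Flatten())
        if out_dim is not None:
            layers.append(nn.Dense(h * w * prev, out_dim, rng))
        return nn.Sequential(layers)

    def _build(self, cfg: ModelConfig, rng: np.random.Generator):
        if cfg.design == "dnn":
            return self._dense_stack(cfg.n_features, cfg.hidden, cfg.dropout, rng, N_CLASSES)
        if cfg.design == "cnn":
            return self._conv_stack(cfg.image_shape, cfg.conv_filters, rng, N_CLASSES)
        # cdnn: feature branch ends at its last hidden width, the conv
        # branch is projected to the same width, and a feedforward head
        # maps the concatenation to the 6-way softmax.
        feat = self._dense_stack(cfg.n_features, cfg.hidden, cfg.dropout, rng, None)
        conv = self._conv_stack(cfg.image_shape, cfg.conv_filters, rng, cfg.hidden[-1])
        head = self._dense_stack(2 * cfg.hidden[-1], (cfg.hidden[-1],), cfg.dropout, rng, N_CLASSES)
        return nn.TwoBranch(feat, conv, head)

    # --- data plumbing ------------------------------------------------------

    def _fit_scaler(self, features: np.ndarray) -> None:
        self.scaler_mean = features.mean(axis=0)
        std = features.std(axis=0)
        self.scaler_std = np.where(std > 1e-12, std, 1.0)

    def _prep(self, data: Dataset):
        cfg = self.config
        feats = imgs = None
        if cfg.design in ("dnn", "cdnn"):
            if data.features is None:
                raise ValueError(f"{cfg.design} needs a feature matrix")
            if data.features.shape[1] != cfg.n_features:
                raise ValueError(
                    f"feature width {data.features.shape[1]} != configured {cfg.n_features}"
                )
            if self.scaler_mean is None:
                self._fit_scaler(data.features)
            feats = (data.features - self.scaler_mean) / self.scaler_std
        if cfg.design in ("cnn", "cdnn"):
            if data.images is None:
                raise ValueError(f"{cfg.design} needs an image stack")
            if tuple(data.images.shape[1:]) != tuple(cfg.image_shape):
                raise ValueError(
                    f"image shape {data.images.shape[1:]} != configured {cfg.image_shape}"
                )
            imgs = data.images.astype(np.float64) / 255.0 - 0.5
        if cfg.design == "dnn":
            return feats
        if cfg.design == "cnn":
            return imgs
        return (feats, imgs)

    def _forward(self, x, train=False):
        return self.net.forward(x, train=train)

    # --- training / inference ----------------------------------------------

    def fit_epochs(self, data: Dataset, epochs: int) -> None:
        """Run `epochs` passes of minibatch Adam over `data` (no checkpointing)."""
        x = self._prep(data)
        y = data.labels
        n = len(data)
        for _ in range(epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, self.config.batch_size):
                idx = order[start : start + self.config.batch_size]
                xb = (x[0][idx], x[1][idx]) if isinstance(x, tuple) else x[idx]
                logits = self._forward(xb, train=True)
                _, dlogits = nn.cross_entropy_grad(logits, y[idx])
                self.net.backward(dlogits)
                self.optimizer.step(self.net.grads)
            self.epochs_trained += 1

    def predict_proba(self, features: np.ndarray | None = None,
                      images: np.ndarray | None = None) -> np.ndarray:
        """Class probabilities, one row per item, rows summing to 1."""
        n = features.shape[0] if features is not None else images.shape[0]
        data = Dataset(labels=np.zeros(n, dtype=np.int64), features=features, images=images)
        if self.scaler_mean is None and self.config.design in ("dnn", "cdnn"):
            raise ValueError("model has not been trained (no feature scaler fitted)")
        x = self._prep(data)
        # batch inference to bound memory on image stacks
        out = []
        for start in range(0, n, 64):
            xb = (
                (x[0][start : start + 64], x[1][start : start + 64])
                if isinstance(x, tuple)
                else x[start : start + 64]
            )
            out.append(nn.softmax(self._forward(xb, train=False)))
        return np.vstack(out)

    def predict(self, features=None, images=None) -> np.ndarray:
        # np.argmax breaks ties toward the lowest class index
        return np.argmax(self.predict_proba(features, images), axis=1)

    def input_gradient(self, images: np.ndarray, features: np.ndarray | None = None) -> np.ndarray:
        """Gradient of each item's predicted-class logit w.r.t. its image pixels."""
        cfg = self.config
        if cfg.design == "dnn":
            raise ValueError("saliency w.r.t. images requires a cnn or cdnn design")
        n = images.shape[0]
        data = Dataset(labels=np.zeros(n, dtype=np.int64), features=features, images=images)
        x = self._prep(data)
        logits = self._forward(x, train=False)
        dout = np.zeros_like(logits)
        dout[np.arange(n), logits.argmax(axis=1)] = 1.0
        dx = self.net.backward(dout)
        return dx[1] if isinstance(dx, tuple) else dx


def build_model(config: ModelConfig) -> TrainedModel:
    """Instantiate an untrained classifier; seeded, so construction is repeatable."""
    return TrainedModel(config)


def train(model: TrainedModel, train_data: Dataset, val_data: Dataset,
          epochs: int | None = None) -> TrainedModel:
    """Train with per-epoch validation and best-epoch checkpointing.

    After every epoch the validation split is scored (plain accuracy and
    balanced accuracy); at the end the weights from the best-plain-accuracy
    epoch are restored.  `epochs` defaults to the config's max_epochs.
    """
    if len(train_data) == 0 or len(val_data) == 0:
        raise ValueError("train and validation partitions must be non-empty")
    epochs = epochs if epochs is not None else model.config.max_epochs
    best_acc, best_weights = -1.0, None
    for _ in range(epochs):
        model.fit_epochs(train_data, 1)
        proba = model.predict_proba(val_data.features, val_data.images)
        pred = proba.argmax(axis=1)
        acc = float(np.mean(pred == val_data.labels))
        bac = _bac_from_predictions(val_data.labels, pred)
        model.history.append({"epoch": model.epochs_trained, "val_accuracy": acc, "val_bac": bac})
        if acc > best_acc:
            best_acc, best_weights = acc, nn.get_weights(model.net)
    if best_weights is not None:
        nn.set_weights(model.net, best_weights)
    return model


def _bac_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    recalls = []
    for c in np.unique(y_true):
        mask = y_true == c
        recalls.append(float(np.mean(y_pred[mask] == c)))
    return float(np.mean(recalls))


def predict_proba(model: TrainedModel, features=None, images=None) -> np.ndarray:
    """Functional alias for :meth:`TrainedModel.predict_proba`."""
    return model.predict_proba(features=features, images=images)


# --- Gaussian-process hyperparameter search ---------------------------------


@dataclass(frozen=True)
class HyperparameterSpace:
    """Search ranges for :func:`tune`.

    `discrete` maps a config field to an explicit list of choices;
    `continuous` maps a field to (low, high, scale) with scale "linear" or
    "log".  The defaults give a conventional, desk-scale search box.
    """

    discrete: dict = field(default_factory=lambda: {
        "depth": [1, 2, 3, 4],
        "width": [32, 64, 128, 256, 512],
        "batch_size": [16, 32, 64],
    })
    continuous: dict = field(default_factory=lambda: {
        "dropout": (0.0, 0.5, "linear"),
        "learning_rate": (1e-4, 1e-2, "log"),
    })
    budget: int = 15

    def __post_init__(self) -> None:
        for name, choices in self.discrete.items():
            if len(choices) == 0:
                raise ValueError(f"empty choice list for {name!r}")
        for name, (lo, hi, scale) in self.continuous.items():
            if not lo < hi:
                raise ValueError(f"empty range for {name!r}")
            if scale not in ("linear", "log"):
                raise ValueError(f"scale for {name!r} must be linear|log")

    @property
    def dim(self) -> int:
        return len(self.discrete) + len(self.continuous)

    def decode(self, z: np.ndarray) -> dict:
        """Map a unit-cube point to concrete hyperparameter values."""
        out = {}
        i = 0
        for name, choices in self.discrete.items():
            out[name] = choices[min(int(z[i] * len(choices)), len(choices) - 1)]
            i += 1
        for name, (lo, hi, scale) in self.continuous.items():
            if scale == "log":
                out[name] = float(np.exp(np.log(lo) + z[i] * (np.log(hi) - np.log(lo))))
            else:
                out[name] = float(lo + z[i] * (hi - lo))
            i += 1
        return out


def gp_maximize(objective: Callable[[np.ndarray], float], dim: int, budget: int,
                seed: int, n_initial: int | None = None,
                n_candidates: int = 256) -> tuple[np.ndarray, float]:
    """Maximize a black-box function on the unit cube by GP + expected improvement.

    Seeds everything, evaluates `n_initial` space-filling points, then
    repeatedly fits a Matern-5/2 Gaussian process to the observations and
    evaluates the candidate with the highest expected improvement.
    Returns (best point, best observed value).
    """
    if budget < 5:
        raise ValueError(f"search budget must be at least 5, got {budget}")
    rng = np.random.default_rng(seed)
    n_initial = n_initial if n_initial is not None else min(budget, max(3, budget // 3))
    X = list(rng.random((n_initial, dim)))
    y = [float(objective(x)) for x in X]

    # Fixed kernel hyperparameters: deterministic, and with a handful of
    # observations marginal-likelihood fitting is noisier than a sensible
    # prior length scale anyway.
    kernel = ConstantKernel(1.0, "fixed") * Matern(length_scale=0.25 * np.ones(dim),
                                                   length_scale_bounds="fixed", nu=2.5) \
        + WhiteKernel(1e-6, noise_level_bounds="fixed")
    while len(y) < budget:
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True, optimizer=None,
                                      random_state=int(rng.integers(2**31)))
        gp.fit(np.array(X), np.array(y))
        cand = rng.random((n_candidates, dim))
        mu, sd = gp.predict(cand, return_std=True)
        best = max(y)
        sd = np.maximum(sd, 1e-12)
        imp = mu - best - 1e-3
        zsc = imp / sd
        ei = imp * norm.cdf(zsc) + sd * norm.pdf(zsc)
        x_next = cand[int(np.argmax(ei))]
        X.append(x_next)
        y.append(float(objective(x_next)))
    k = int(np.argmax(y))
    return X[k], y[k]


def tune(space: HyperparameterSpace, train_data: Dataset, design: str,
         seed: int = 0, base_config: ModelConfig | None = None,
         tune_epochs: int = 2) -> ModelConfig:
    """Search the hyperparameter space for one design on its training data.

    Each evaluation holds out 20% of `train_data` (stratified, seeded),
    trains a candidate briefly and scores validation accuracy; the GP
    surrogate drives the sequence.  Returns the best observed config.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}")
    base = base_config or ModelConfig(
        design=design,
        n_features=None if train_data.features is None else train_data.features.shape[1],
        image_shape=None if train_data.images is None else tuple(train_data.images.shape[1:]),
        seed=seed,
    )
    idx_tr, idx_va = train_test_split(
        np.arange(len(train_data)), test_size=0.2, stratify=train_data.labels,
        random_state=seed % (2**31),
    )
    tr, va = train_data.subset(idx_tr), train_data.subset(idx_va)

    def objective(z: np.ndarray) -> float:
        params = space.decode(z)
        cfg = replace(
            base,
            hidden=tuple([params["width"]] * params["depth"]),
            dropout=params["dropout"],
            learning_rate=params["learning_rate"],
            batch_size=params["batch_size"],
        )
        model = build_model(cfg)
        train(model, tr, va, epochs=tune_epochs)
        return max(h["val_accuracy"] for h in model.history)

    z_best, _ = gp_maximize(objective, space.dim, space.budget, seed)
    params = space.decode(z_best)
    return replace(
        base,
        hidden=tuple([params["width"]] * params["depth"]),
        dropout=params["dropout"],
        learning_rate=params["learning_rate"],
        batch_size=params["batch_size"],
    )
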