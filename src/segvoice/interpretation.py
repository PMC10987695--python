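"""Model interpretation: average saliency maps and time-segment Shapley values.

Two complementary views of *when* in the 1.5 s window the classifiers
look:

* the **average saliency map** — the absolute gradient of the predicted
  class score with respect to the spectrogram pixels, averaged over a set
  of images — shows which time-frequency regions drive the convolutional
  branch;
* **time-segment Shapley values** group the inputs into 48 equal time
  intervals and estimate each interval's average marginal contribution to
  the predicted-class probability by permutation sampling, with masked
  intervals replaced by the dataset mean.

The permutation estimator is model-agnostic: any callable mapping an input
matrix to per-item scores can be attributed, which is also how the unit
tests check it against exact closed-form Shapley values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FrameSpec, feature_time_map
from .models import TrainedModel
from .spectrogram import HEIGHT, WIDTH


@dataclass
class SaliencyMap:
    """Pixel-plane saliency averaged over `n_images` spectrograms."""

    values: np.ndarray  # (HEIGHT, WIDTH), non-negative
    n_images: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (HEIGHT, WIDTH):
            raise ValueError(f"saliency map must be {HEIGHT}x{WIDTH}, got {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("saliency values must be non-negative")


@dataclass
class TimeSegmentAttribution:
    """Shapley attribution over consecutive time segments of the window."""

    values: np.ndarray  # (n_segments,)
    boundaries: np.ndarray  # (n_segments + 1,) in seconds
    baseline_value: float
    full_value: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.boundaries = np.asarray(self.boundaries, dtype=np.float64)
        if self.boundaries.size != self.values.size + 1:
            raise ValueError("need n_segments + 1 boundaries")

    def __len__(self) -> int:
        return self.values.size


def average_saliency(model: TrainedModel, images: np.ndarray,
                     features: np.ndarray | None = None,
                     batch: int = 16) -> SaliencyMap:
    """Mean absolute pixel gradient of the predicted-class score.

    Per image, the gradient of the winning logit is taken with respect to
    the pixels and its channel-summed absolute value forms that image's
    saliency plane; the output averages the planes.  Requires a design
    with a convolutional branch (cnn or cdnn).
    """
    if model.config.design == "dnn":
        raise ValueError("saliency maps require a cnn or cdnn design")
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    if images.shape[0] < 1:
        raise ValueError("need at least one image")
    total = np.zeros(images.shape[1:3])
    for start in range(0, images.shape[0], batch):
        imgs = images[start : start + batch]
        feats = None if features is None else features[start : start + batch]
        grad = model.input_gradient(imgs, features=feats)
        total += np.abs(grad).sum(axis=3).sum(axis=0)
    return SaliencyMap(values=total / images.shape[0], n_images=images.shape[0])


def segment_boundaries(duration: float, n_samples: int, n_segments: int = 48) -> np.ndarray:
    """Segment edges in seconds; the division remainder joins the last segment."""
    seg_len = n_samples // n_segments
    edges = np.arange(n_segments + 1, dtype=np.float64) * seg_len
    edges[-1] = n_samples
    return edges * (duration / n_samples)


def shapley_sampling(predict, X: np.ndarray, groups: np.ndarray,
                     baseline: np.ndarray, n_groups: int, draws: int = 30,
                     seed: int = 0) -> tuple[np.ndarray, float, float]:
    """Permutation-sampling Shapley values for grouped input columns.

    `predict` maps a (n, d) matrix to n scores; `groups` assigns every
    column to a coalition in [0, n_groups) or -1 for always-present
    context; `baseline` is the masking row (typically the dataset mean).
    For each sampled permutation the coalitions are revealed one by one
    and the score increments are accumulated — the telescoping sum makes
    the estimates exactly efficient: they sum to f(x) - f(baseline).
    Each draw traverses the sampled permutation and its reverse
    (antithetic pairing), which reduces variance and makes the two-
    coalition case exact.

    Returns (per-group values averaged over rows of X, mean baseline
    score, mean full score).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    baseline = np.asarray(baseline, dtype=np.float64).ravel()
    if X.shape[1] != baseline.size or X.shape[1] != groups.size:
        raise ValueError("X, baseline and groups must agree on the number of columns")
    rng = np.random.default_rng(seed)
    n, d = X.shape
    masks = [groups == g for g in range(n_groups)]

    contrib = np.zeros((n, n_groups))
    base_rows = np.tile(baseline, (n, 1))
    # context columns (group -1) are never masked
    ctx = groups < 0
    base_rows[:, ctx] = X[:, ctx]
    v_base = float(np.mean(predict(base_rows)))
    v_full = float(np.mean(predict(X)))
    for _ in range(draws):
        order = rng.permutation(n_groups)
        for walk in (order, order[::-1]):
            current = base_rows.copy()
            prev = predict(current)
            for g in walk:
                current[:, masks[g]] = X[:, masks[g]]
                now = predict(current)
                contrib[:, g] += now - prev
                prev = now
    contrib /= 2 * draws
    return contrib.mean(axis=0), v_base, v_full


def _model_predict_fn(model: TrainedModel, on: str, target_class: np.ndarray):
    # The explained quantity is the probability of the class predicted on
    # the *unmasked* input, held fixed while coalitions are masked.
    if on == "features":
        def predict(X):
            proba = model.predict_proba(features=X)
            return proba[np.arange(X.shape[0]), target_class]
        return predict
    def predict(Ximg_flat):
        imgs = Ximg_flat.reshape((-1,) + tuple(model.config.image_shape))
        proba = model.predict_proba(images=imgs)
        return proba[np.arange(imgs.shape[0]), target_class]
    return predict


def shap_time_segments(model: TrainedModel, inputs: np.ndarray,
                       n_segments: int = 48, draws: int = 20, seed: int = 0,
                       on: str = "features", duration: float = 1.5,
                       n_samples: int = 24_000,
                       spec: FrameSpec | None = None) -> TimeSegmentAttribution:
    """Attribute the predicted-class probability to 48 time segments.

    `on="features"` groups feature-vector entries by the time of their
    frame/window (bin-wise summaries stay as unmasked context);
    `on="images"` groups spectrogram pixel columns by time.  Masked
    segments are replaced by the dataset mean of `inputs`, and the
    attribution is averaged over all rows.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    inputs = np.asarray(inputs)
    if inputs.shape[0] < 1:
        raise ValueError("need at least one input")
    if on == "features":
        X = inputs.astype(np.float64)
        fmap = feature_time_map(n_samples, spec, n_segments)
        if fmap.size != X.shape[1]:
            raise ValueError(
                f"feature width {X.shape[1]} does not match the battery's "
                f"{fmap.size} entries for a {n_samples}-sample window"
            )
        groups = fmap
    elif on == "images":
        h, w, c = model.config.image_shape
        if inputs.shape[1:] != (h, w, c):
            raise ValueError(f"images must be {h}x{w}x{c}, got {inputs.shape[1:]}")
        col_seg = np.minimum(np.arange(w) * n_segments // w, n_segments - 1)
        groups = np.broadcast_to(col_seg[None, :, None], (h, w, c)).ravel()
        X = inputs.reshape(inputs.shape[0], -1).astype(np.float64)
    else:
        raise ValueError(f"on must be features|images, got {on!r}")

    baseline = X.mean(axis=0)
    if on == "features":
        target_class = model.predict(features=inputs)
    else:
        target_class = model.predict(images=inputs)
    predict = _model_predict_fn(model, on, target_class)
    values, v_base, v_full = shapley_sampling(
        predict, X, groups, baseline, n_segments, draws=draws, seed=seed
    )
    return TimeSegmentAttribution(
        values=values,
        boundaries=segment_boundaries(duration, n_samples, n_segments),
        baseline_value=v_base,
        full_value=v_full,
    )
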