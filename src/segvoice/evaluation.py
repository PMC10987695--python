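"""Bayesian evaluation stack: balanced accuracy, cross-validation,
Independent Validation with beta-posterior updating, and model/human
comparison.

The central object is the conjugate beta posterior over a classifier's
accuracy: starting from a beta(1, 1) flat prior, every correct prediction
increments alpha and every incorrect one increments beta.  Because a beta
prior is conjugate to the binomial likelihood, the posterior after any
sequence of predictions is simply beta(1 + correct, 1 + incorrect), while
the *sequential* updating scheme lets accuracy be tracked as data streams
in.  Posteriors are compared by their overlap coefficient (near zero means
practically disjoint performance) and by the probability that one
classifier outperforms another.

Independent Validation is prequential: the model trains on a small initial
partition, then repeatedly predicts the next chunk of unseen items *before*
absorbing them into the training set, so every prediction is out-of-sample
at the moment it is made.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate
from scipy.stats import beta as beta_dist
from sklearn.model_selection import StratifiedKFold, train_test_split

from .labels import N_CLASSES
from .models import Dataset, ModelConfig, TrainedModel, build_model, train


@dataclass(frozen=True)
class BetaPosterior:
    """Parameters of a beta distribution over an accuracy in [0, 1]."""

    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        a, b = self.alpha, self.beta
        return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))))

    def pdf(self, x):
        return beta_dist.pdf(x, self.alpha, self.beta)

    def cdf(self, x):
        return beta_dist.cdf(x, self.alpha, self.beta)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.beta(self.alpha, self.beta, size=n)


def beta_update(p: BetaPosterior, successes: int, failures: int) -> BetaPosterior:
    """Conjugate update: beta(a, b) + (s, f) -> beta(a + s, b + f)."""
    if successes < 0 or failures < 0:
        raise ValueError("success/failure counts must be non-negative")
    return BetaPosterior(p.alpha + successes, p.beta + failures)


def beta_map(p: BetaPosterior) -> float:
    """Maximum a-posteriori estimate: (a-1)/(a+b-2) when the mode exists.

    For a <= 1 or b <= 1 the density has no interior mode and the mean is
    returned instead (so the flat beta(1,1) prior maps to 0.5).
    """
    if p.alpha > 1 and p.beta > 1:
        return (p.alpha - 1) / (p.alpha + p.beta - 2)
    return p.mean


def prob_greater(a: BetaPosterior, b: BetaPosterior, draws: int = 100_000,
                 seed: int = 0, method: str = "mc") -> float:
    """P(X_a > X_b) for independent beta variables.

    `method="mc"` draws seeded Monte-Carlo samples (requires >= 10,000
    draws); `method="quad"` integrates f_b(x) * (1 - F_a(x)) numerically
    and is deterministic.
    """
    if method == "quad":
        val, _ = integrate.quad(lambda x: b.pdf(x) * (1.0 - a.cdf(x)), 0.0, 1.0, limit=200)
        return float(min(max(val, 0.0), 1.0))
    if method != "mc":
        raise ValueError(f"method must be mc|quad, got {method!r}")
    if draws < 10_000:
        raise ValueError(f"Monte-Carlo comparison needs >= 10,000 draws, got {draws}")
    rng = np.random.default_rng(seed)
    return float(np.mean(a.sample(draws, rng) > b.sample(draws, rng)))


def overlap_coefficient(a: BetaPosterior, b: BetaPosterior, grid: int = 8193) -> float:
    """Overlap of two beta densities: integral of min(f_a, f_b) over [0, 1].

    Uses the identity min = (f_a + f_b - |f_a - f_b|) / 2 and integrates
    |f_a - f_b| exactly on each sign-constant interval via the CDFs; only
    the crossing locations are grid-resolved, so the result is accurate
    even for sharply peaked densities.
    """
    x = np.linspace(0.0, 1.0, grid)
    diff_sign = np.sign(a.pdf(x[1:-1]) - b.pdf(x[1:-1]))
    # breakpoints where f_a - f_b changes sign
    change = np.nonzero(np.diff(diff_sign) != 0)[0]
    cuts = np.concatenate([[0.0], x[1:-1][change], [1.0]])
    total_abs = 0.0
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        dFa = a.cdf(hi) - a.cdf(lo)
        dFb = b.cdf(hi) - b.cdf(lo)
        total_abs += abs(dFa - dFb)
    return float(min(max(1.0 - 0.5 * total_abs, 0.0), 1.0))


# --- balanced accuracy and cross-validation ---------------------------------


def balanced_accuracy(confusion: np.ndarray) -> float:
    """Mean per-class recall from a (true x predicted) count matrix."""
    confusion = np.asarray(confusion, dtype=np.float64)
    row_sums = confusion.sum(axis=1)
    if np.any(row_sums == 0):
        empty = np.nonzero(row_sums == 0)[0].tolist()
        raise ValueError(f"classes {empty} have no true instances; recall undefined")
    return float(np.mean(np.diag(confusion) / row_sums))


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    out = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(out, (np.asarray(y_true), np.asarray(y_pred)), 1)
    return out


@dataclass
class FoldResult:
    fold: int
    bac: float
    confusion: np.ndarray


def run_cv(dataset: Dataset, config: ModelConfig, k: int = 10, seed: int = 0,
           epochs: int | None = None) -> list[FoldResult]:
    """Stratified k-fold cross-validation of one classifier design.

    Each fold trains a fresh seeded model on the remaining folds (with 20%
    of the training part held out for per-epoch validation) and scores the
    fold by balanced accuracy over its confusion matrix.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(dataset) < k:
        raise ValueError(f"dataset of {len(dataset)} items cannot fill {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    results = []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(len(dataset)), dataset.labels)):
        tr_sub, va_sub = train_test_split(
            tr_idx, test_size=0.2, stratify=dataset.labels[tr_idx],
            random_state=(seed + fold) % (2**31),
        )
        model = build_model(replace(config, seed=config.seed + fold))
        train(model, dataset.subset(tr_sub), dataset.subset(va_sub), epochs=epochs)
        test = dataset.subset(te_idx)
        pred = model.predict(test.features, test.images)
        conf = confusion_matrix(test.labels, pred)
        present = conf.sum(axis=1) > 0
        bac = float(np.mean(np.diag(conf)[present] / conf.sum(axis=1)[present]))
        results.append(FoldResult(fold=fold, bac=bac, confusion=conf))
    return results


# --- Independent Validation -------------------------------------------------


@dataclass
class ChunkRecord:
    index: int
    correct: np.ndarray  # per-item booleans, in stream order
    posterior: BetaPosterior  # running posterior after this chunk
    val_accuracy: float


@dataclass
class IVTrace:
    """Full record of one Independent Validation run."""

    chunks: list[ChunkRecord] = field(default_factory=list)
    prior: BetaPosterior = field(default_factory=BetaPosterior)
    n_init: int = 0
    n_val: int = 0
    n_stream: int = 0

    @property
    def posterior(self) -> BetaPosterior:
        return self.chunks[-1].posterior if self.chunks else self.prior

    @property
    def n_correct(self) -> int:
        return int(sum(c.correct.sum() for c in self.chunks))

    @property
    def n_predicted(self) -> int:
        return int(sum(c.correct.size for c in self.chunks))


def run_independent_validation(
    dataset: Dataset,
    config: ModelConfig,
    chunk: int = 16,
    init_frac: float = 0.10,
    val_frac: float = 0.10,
    prior: BetaPosterior | None = None,
    seed: int = 0,
    epochs_per_chunk: int = 1,
    full_retrain: bool = False,
) -> IVTrace:
    """Prequential evaluation with sequential beta updating.

    The dataset is split (stratified, seeded) into an initial training
    partition (`init_frac`), a fixed validation partition (`val_frac`) and
    a stream.  After initial training, the stream is consumed in chunks of
    `chunk` items: the model predicts the chunk, the posterior absorbs the
    correct/incorrect counts, and the chunk joins the training set, after
    which optimization continues for `epochs_per_chunk` passes (or from
    scratch when `full_retrain` is set).  Validation accuracy is recorded
    at every step to monitor overfitting.
    """
    prior = prior or BetaPosterior(1.0, 1.0)
    n = len(dataset)
    n_init = int(round(init_frac * n))
    n_val = int(round(val_frac * n))
    if n_init < N_CLASSES or n_val < N_CLASSES or n - n_init - n_val < chunk:
        raise ValueError(
            f"dataset of {n} items is too small for init_frac={init_frac}, "
            f"val_frac={val_frac}, chunk={chunk}; need at least "
            f"{N_CLASSES * 2 + chunk} items with every class represented"
        )
    rng = np.random.default_rng(seed)
    idx_rest, idx_init = train_test_split(
        np.arange(n), test_size=n_init, stratify=dataset.labels, random_state=seed % (2**31)
    )
    idx_stream, idx_val = train_test_split(
        idx_rest, test_size=n_val, stratify=dataset.labels[idx_rest],
        random_state=(seed + 1) % (2**31),
    )
    rng.shuffle(idx_stream)

    train_set = dataset.subset(idx_init)
    val_set = dataset.subset(idx_val)
    model = build_model(config)
    train(model, train_set, val_set)

    trace = IVTrace(prior=prior, n_init=n_init, n_val=n_val, n_stream=idx_stream.size)
    posterior = prior
    for ci, start in enumerate(range(0, idx_stream.size, chunk)):
        chunk_idx = idx_stream[start : start + chunk]
        batch = dataset.subset(chunk_idx)
        pred = model.predict(batch.features, batch.images)
        correct = pred == batch.labels
        posterior = beta_update(posterior, int(correct.sum()), int((~correct).sum()))
        train_set = train_set.concat(batch)
        if full_retrain:
            model = build_model(config)
            train(model, train_set, val_set)
        else:
            model.fit_epochs(train_set, epochs_per_chunk)
        val_pred = model.predict(val_set.features, val_set.images)
        val_acc = float(np.mean(val_pred == val_set.labels))
        trace.chunks.append(
            ChunkRecord(index=ci, correct=correct, posterior=posterior, val_accuracy=val_acc)
        )
    return trace


def random_classifier_posterior(n_items: int, n_classes: int = N_CLASSES,
                                prior: BetaPosterior | None = None,
                                seed: int = 0) -> BetaPosterior:
    """Posterior of a uniformly guessing classifier after `n_items` predictions.

    Simulates guesses with success probability 1/n_classes and applies the
    conjugate update.  The analytic expectation of the success rate is
    exactly 1/n_classes regardless of the label distribution, because the
    guess is independent of the label.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    prior = prior or BetaPosterior(1.0, 1.0)
    rng = np.random.default_rng(seed)
    correct = int(np.sum(rng.random(n_items) < 1.0 / n_classes))
    return beta_update(prior, correct, n_items - correct)


# --- human comparison -------------------------------------------------------


@dataclass(frozen=True)
class HumanRatings:
    """Per-emotion correct/total recognition counts from a listening study."""

    counts: dict  # label -> (correct, total)

    def __post_init__(self) -> None:
        for label, (correct, total) in self.counts.items():
            if correct < 0 or total < 0 or correct > total:
                raise ValueError(f"invalid counts for {label!r}: {correct}/{total}")


def human_posteriors(ratings: HumanRatings,
                     prior: BetaPosterior | None = None) -> dict[str, BetaPosterior]:
    """Per-emotion beta posteriors from binomial recognition counts.

    Emotions with zero total ratings are excluded with a warning — there
    is no evidence to update on, so comparing them would be meaningless.
    """
    prior = prior or BetaPosterior(1.0, 1.0)
    out = {}
    for label, (correct, total) in ratings.counts.items():
        if total == 0:
            warnings.warn(f"emotion {label!r} has no ratings; excluded from comparison")
            continue
        out[label] = beta_update(prior, correct, total - correct)
    return out


def per_class_recall_posteriors(confusion: np.ndarray, labels: list[str],
                                prior: BetaPosterior | None = None) -> dict[str, BetaPosterior]:
    """Per-class recall posteriors from a confusion matrix (for human comparison)."""
    prior = prior or BetaPosterior(1.0, 1.0)
    confusion = np.asarray(confusion)
    out = {}
    for i, label in enumerate(labels):
        total = int(confusion[i].sum())
        if total == 0:
            warnings.warn(f"class {label!r} has no instances; excluded")
            continue
        out[label] = beta_update(prior, int(confusion[i, i]), total - int(confusion[i, i]))
    return out


def compare_posteriors(a: BetaPosterior, b: BetaPosterior, draws: int = 100_000,
                       seed: int = 0) -> dict:
    """Headline comparison of two accuracy posteriors.

    Reports both the overlap coefficient (near-zero overlap means the two
    performances are practically disjoint) and P(a > b) by Monte Carlo.
    """
    return {
        "map_a": beta_map(a),
        "map_b": beta_map(b),
        "sd_a": a.sd,
        "sd_b": b.sd,
        "overlap": overlap_coefficient(a, b),
        "p_a_greater": prob_greater(a, b, draws=draws, seed=seed),
    }
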