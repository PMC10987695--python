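"""Beta-posterior machinery, balanced accuracy, cross-validation and
Independent Validation bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segvoice import evaluation as ev
from segvoice.models import Dataset, ModelConfig


def _random_features_dataset(n=360, d=50, seed=1):
    """Cheap stand-in dataset (random features) for bookkeeping checks."""
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(6), n // 6)
    return Dataset(labels=y, features=rng.standard_normal((n, d)))


FAST_DNN = dict(design="dnn", n_features=50, hidden=(32,), seed=0)


class TestBetaPosterior:
    def test_conjugate_update(self):
        post = ev.beta_update(ev.BetaPosterior(1, 1), 3, 1)
        assert (post.alpha, post.beta) == (4, 2)

    def test_zero_update_is_identity(self):
        p = ev.BetaPosterior(5, 7)
        assert ev.beta_update(p, 0, 0) == p

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ev.beta_update(ev.BetaPosterior(), -1, 0)

    @settings(max_examples=50, deadline=None)
    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 50), st.integers(0, 50)), min_size=1, max_size=6
        )
    )
    def test_update_order_is_irrelevant(self, counts):
        """Any interleaving with the same aggregate counts gives the same posterior."""
        sequential = ev.BetaPosterior(1, 1)
        for s, f in counts:
            sequential = ev.beta_update(sequential, s, f)
        total_s = sum(c[0] for c in counts)
        total_f = sum(c[1] for c in counts)
        assert sequential == ev.beta_update(ev.BetaPosterior(1, 1), total_s, total_f)

    @pytest.mark.parametrize(
        "alpha, beta, expected",
        [(2, 2, 0.5), (10, 4, 0.75), (1, 1, 0.5)],  # last: mean fallback for flat prior
    )
    def test_map_closed_form(self, alpha, beta, expected):
        assert ev.beta_map(ev.BetaPosterior(alpha, beta)) == pytest.approx(expected)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ev.BetaPosterior(0, 1)


class TestProbGreater:
    def test_identical_posteriors_give_half(self):
        p = ev.BetaPosterior(7, 3)
        assert ev.prob_greater(p, p, seed=0) == pytest.approx(0.5, abs=0.01)

    def test_analytic_case_five_sixths(self):
        a, b = ev.BetaPosterior(2, 1), ev.BetaPosterior(1, 2)
        assert ev.prob_greater(a, b, method="quad") == pytest.approx(5 / 6, abs=1e-6)
        assert ev.prob_greater(a, b, seed=0) == pytest.approx(5 / 6, abs=0.01)

    def test_stochastic_dominance(self):
        a, b = ev.BetaPosterior(50, 10), ev.BetaPosterior(10, 50)
        assert ev.prob_greater(a, b, method="quad") > 0.99

    def test_monte_carlo_matches_quadrature(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a = ev.BetaPosterior(rng.uniform(0.5, 50), rng.uniform(0.5, 50))
            b = ev.BetaPosterior(rng.uniform(0.5, 50), rng.uniform(0.5, 50))
            mc = ev.prob_greater(a, b, draws=100_000, seed=1)
            quad = ev.prob_greater(a, b, method="quad")
            assert abs(mc - quad) < 0.01

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="10,000"):
            ev.prob_greater(ev.BetaPosterior(), ev.BetaPosterior(), draws=100)


class TestOverlap:
    def test_identical_posteriors_overlap_fully(self):
        p = ev.BetaPosterior(30, 12)
        assert ev.overlap_coefficient(p, p) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_posteriors_overlap_near_zero(self):
        assert ev.overlap_coefficient(ev.BetaPosterior(500, 10), ev.BetaPosterior(10, 500)) < 1e-3

    def test_symmetry(self):
        a, b = ev.BetaPosterior(20, 5), ev.BetaPosterior(8, 9)
        assert ev.overlap_coefficient(a, b) == pytest.approx(ev.overlap_coefficient(b, a))

    def test_agrees_with_direct_quadrature(self):
        from scipy import integrate

        rng = np.random.default_rng(7)
        for _ in range(5):
            a = ev.BetaPosterior(rng.uniform(1, 40), rng.uniform(1, 40))
            b = ev.BetaPosterior(rng.uniform(1, 40), rng.uniform(1, 40))
            direct, _ = integrate.quad(
                lambda x: np.minimum(a.pdf(x), b.pdf(x)), 0, 1, limit=200
            )
            assert ev.overlap_coefficient(a, b) == pytest.approx(direct, abs=1e-4)


class TestBalancedAccuracy:
    def test_identity_confusion_is_perfect(self):
        assert ev.balanced_accuracy(np.eye(6) * 10) == 1.0

    def test_mean_of_recalls(self):
        confusion = np.array([[5, 5], [0, 10]])
        assert ev.balanced_accuracy(confusion) == pytest.approx(0.75)

    def test_matches_sklearn_on_random_predictions(self):
        from sklearn.metrics import balanced_accuracy_score

        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 6, 300)
        y_pred = rng.integers(0, 6, 300)
        conf = ev.confusion_matrix(y_true, y_pred)
        assert ev.balanced_accuracy(conf) == pytest.approx(
            balanced_accuracy_score(y_true, y_pred)
        )

    def test_empty_class_rejected(self):
        confusion = np.zeros((6, 6))
        confusion[0, 0] = 5
        with pytest.raises(ValueError, match="no true instances"):
            ev.balanced_accuracy(confusion)

    def test_uniform_guessing_expectation(self):
        """Uniform random predictions over balanced classes average BAC 1/6."""
        rng = np.random.default_rng(3)
        bacs = []
        for _ in range(50):
            y_true = np.repeat(np.arange(6), 60)
            y_pred = rng.integers(0, 6, 360)
            bacs.append(ev.balanced_accuracy(ev.confusion_matrix(y_true, y_pred)))
        assert np.mean(bacs) == pytest.approx(1 / 6, abs=0.01)


class TestCrossValidation:
    def test_fold_arithmetic_and_coverage(self):
        data = _random_features_dataset(n=60)
        results = ev.run_cv(data, ModelConfig(**FAST_DNN), k=10, seed=0, epochs=1)
        assert len(results) == 10
        for r in results:
            assert r.confusion.sum() == 6  # 6 test items per fold
        assert sum(r.confusion.sum() for r in results) == 60  # exact cover

    def test_deterministic_under_seed(self):
        data = _random_features_dataset(n=60)
        a = ev.run_cv(data, ModelConfig(**FAST_DNN), k=5, seed=4, epochs=1)
        b = ev.run_cv(data, ModelConfig(**FAST_DNN), k=5, seed=4, epochs=1)
        assert [r.bac for r in a] == [r.bac for r in b]

    def test_high_separation_beats_chance(self, battery_high):
        X, y = battery_high
        sub = np.concatenate([np.nonzero(y == c)[0][:20] for c in range(6)])
        data = Dataset(labels=y[sub], features=X[sub])
        cfg = ModelConfig(design="dnn", n_features=X.shape[1], seed=0)
        results = ev.run_cv(data, cfg, k=5, seed=0)
        bacs = [r.bac for r in results]
        se = np.std(bacs, ddof=1) / np.sqrt(len(bacs))
        assert np.mean(bacs) > 1 / 6 + 3 * se

    def test_k_too_large_rejected(self):
        data = _random_features_dataset(n=12)
        with pytest.raises(ValueError):
            ev.run_cv(data, ModelConfig(**FAST_DNN), k=13, seed=0)


class TestIndependentValidation:
    def test_chunk_bookkeeping_at_n360(self):
        """n=360 with 10%/10% splits leaves a 288-item stream = 18 chunks of 16."""
        data = _random_features_dataset()
        trace = ev.run_independent_validation(data, ModelConfig(**FAST_DNN), seed=0)
        assert trace.n_init == 36 and trace.n_val == 36 and trace.n_stream == 288
        assert len(trace.chunks) == 18
        assert all(c.correct.size == 16 for c in trace.chunks)

    def test_final_posterior_is_conjugate_over_trace(self):
        data = _random_features_dataset(seed=5)
        trace = ev.run_independent_validation(data, ModelConfig(**FAST_DNN), seed=2)
        post = trace.posterior
        assert post.alpha == 1 + trace.n_correct
        assert post.beta == 1 + (trace.n_predicted - trace.n_correct)

    def test_partition_conservation(self):
        data = _random_features_dataset()
        trace = ev.run_independent_validation(data, ModelConfig(**FAST_DNN), seed=0)
        assert trace.n_init + trace.n_val + trace.n_stream == len(data)

    def test_random_features_stay_at_chance(self):
        data = _random_features_dataset(seed=9)
        trace = ev.run_independent_validation(data, ModelConfig(**FAST_DNN), seed=0)
        post = trace.posterior
        assert abs(ev.beta_map(post) - 1 / 6) < 3 * post.sd

    def test_insufficient_data_rejected(self):
        data = _random_features_dataset(n=30)
        with pytest.raises(ValueError, match="too small"):
            ev.run_independent_validation(data, ModelConfig(**FAST_DNN), seed=0)


class TestRandomClassifier:
    def test_posterior_concentrates_at_one_sixth(self):
        post = ev.random_classifier_posterior(10_000, seed=0)
        assert abs(post.mean - 1 / 6) < 3 * post.sd

    def test_zero_items_rejected(self):
        with pytest.raises(ValueError):
            ev.random_classifier_posterior(0)


class TestHumanComparison:
    def test_counts_become_conjugate_posteriors(self):
        ratings = ev.HumanRatings(counts={"anger": (30, 40)})
        post = ev.human_posteriors(ratings)["anger"]
        assert (post.alpha, post.beta) == (31, 11)

    def test_identical_posteriors_overlap_fully(self):
        ratings = ev.HumanRatings(counts={"joy": (20, 30)})
        human = ev.human_posteriors(ratings)["joy"]
        model = ev.beta_update(ev.BetaPosterior(), 20, 10)
        assert ev.overlap_coefficient(human, model) == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_excluded_with_warning(self):
        ratings = ev.HumanRatings(counts={"fear": (0, 0), "joy": (5, 10)})
        with pytest.warns(UserWarning, match="fear"):
            out = ev.human_posteriors(ratings)
        assert set(out) == {"joy"}

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ev.HumanRatings(counts={"anger": (5, 4)})
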