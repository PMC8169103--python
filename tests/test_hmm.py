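import numpy as np
import pytest

from eventshift.hmm import (
    EventModel,
    ViewingSeries,
    emission_loglik,
    expected_event_curve,
    fit_event_model,
    forward_backward,
    select_n_events,
)
from eventshift.synthetic import generate_subject_viewings, make_ground_truth
from eventshift._utils import zscore_cols, zscore_rows

from conftest import brute_force_posterior


def random_instance(rng, t_len, k, f=4, sigma2=1.3):
    data = rng.standard_normal((f, t_len))
    patterns = zscore_rows(rng.standard_normal((k, f)))
    advance = min(max(k / t_len, 1e-6), 1 - 1e-6)
    model = EventModel(k, patterns, sigma2, advance)
    return ViewingSeries(data, 1.5), model


class TestEmission:
    def test_matching_pattern_maximizes_row(self, rng):
        patterns = zscore_rows(rng.standard_normal((3, 8)))
        model = EventModel(3, patterns, 0.5, 0.3)
        series = ViewingSeries(patterns.T.copy(), 1.5)
        ll = emission_loglik(series, model)
        assert (np.argmax(ll, axis=1) == np.arange(3)).all()

    def test_duplicate_patterns_give_identical_columns(self, rng):
        p = zscore_rows(rng.standard_normal((1, 6)))
        patterns = np.vstack([p, rng.standard_normal((1, 6)), p])
        model = EventModel(3, patterns, 1.0, 0.3)
        series = ViewingSeries(rng.standard_normal((6, 10)), 1.5)
        ll = emission_loglik(series, model)
        np.testing.assert_allclose(ll[:, 0], ll[:, 2], atol=1e-12)

    def test_matches_closed_form_gaussian(self):
        # F=2, sigma^2=1: log N(z; m, I) = -||z-m||^2/2 - log(2*pi)
        data = np.array([[1.0, -1.0], [-1.0, 1.0]])
        patterns = np.array([[1.0, -1.0], [-1.0, 1.0]])
        model = EventModel(2, patterns, 1.0, 0.5)
        ll = emission_loglik(ViewingSeries(data, 1.5), model)
        z = zscore_cols(data)
        expected = np.empty((2, 2))
        for t in range(2):
            for k in range(2):
                expected[t, k] = -0.5 * np.sum(
                    (z[:, t] - patterns[k]) ** 2
                ) - np.log(2 * np.pi)
        np.testing.assert_allclose(ll, expected, atol=1e-12)

    def test_rejects_nonpositive_variance(self, rng):
        series, model = random_instance(rng, 6, 2)
        model.noise_variance = -1.0
        with pytest.raises(ValueError):
            emission_loglik(series, model)


class TestForwardBackward:
    def test_single_event_posterior_is_ones(self, rng):
        series = ViewingSeries(rng.standard_normal((4, 7)), 1.5)
        model = EventModel(1, zscore_rows(rng.standard_normal((1, 4))), 1.0, 0.5)
        post = forward_backward(series, model)
        np.testing.assert_array_equal(post.gamma, np.ones((7, 1)))

    def test_t_equals_k_forces_identity_segmentation(self, rng):
        series, model = random_instance(rng, 5, 5)
        post = forward_backward(series, model)
        np.testing.assert_allclose(post.gamma, np.eye(5), atol=1e-12)

    def test_t_less_than_k_rejected(self, rng):
        series, model = random_instance(rng, 3, 4)
        with pytest.raises(ValueError, match="admissible"):
            forward_backward(series, model)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        t_len = int(rng.integers(4, 13))
        k = int(rng.integers(2, min(t_len, 5)))
        series, model = random_instance(rng, t_len, k)
        post = forward_backward(series, model)
        gamma, ll = brute_force_posterior(series, model)
        assert np.abs(post.gamma - gamma).max() <= 1e-8
        assert post.log_likelihood == pytest.approx(ll, abs=1e-8)

    def test_rows_sum_to_one_and_nonnegative(self, rng):
        series, model = random_instance(rng, 30, 4)
        post = forward_backward(series, model)
        assert (post.gamma >= 0).all()
        np.testing.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_feature_permutation_leaves_posterior_unchanged(self, rng):
        series, model = random_instance(rng, 12, 3, f=6)
        post = forward_backward(series, model)
        perm = rng.permutation(6)
        series_p = ViewingSeries(series.data[perm], 1.5)
        model_p = EventModel(3, model.event_patterns[:, perm], model.noise_variance,
                             model.advance_prob)
        post_p = forward_backward(series_p, model_p)
        np.testing.assert_allclose(post.gamma, post_p.gamma, atol=1e-12)

    def test_time_reversal_reverses_posterior(self, rng):
        series, model = random_instance(rng, 12, 3, f=6)
        post = forward_backward(series, model)
        series_r = ViewingSeries(series.data[:, ::-1].copy(), 1.5)
        model_r = EventModel(3, model.event_patterns[::-1].copy(),
                             model.noise_variance, model.advance_prob)
        post_r = forward_backward(series_r, model_r)
        np.testing.assert_allclose(post.gamma, post_r.gamma[::-1, ::-1], atol=1e-9)


class TestFitEventModel:
    def test_noiseless_recovery_of_boundaries(self):
        truth = make_ground_truth(4, 24, 12, [0.0], noise_sd=0.0, seed=0)
        subs = generate_subject_viewings(truth, 1, mixing="none", seed=1)
        _, posts = fit_event_model(subs[0], 4)
        labels = np.argmax(posts[0].gamma, axis=1)
        expected = np.zeros(24, dtype=int)
        for b in truth.boundaries_by_viewing[0]:
            expected[b:] += 1
        np.testing.assert_array_equal(labels, expected)

    def test_loglik_monotone_nondecreasing(self, rng):
        data = [ViewingSeries(rng.standard_normal((8, 25)), 1.5) for _ in range(2)]
        history = []
        fit_event_model(data, 3, max_iter=40, tol=0.0, loglik_history=history)
        diffs = np.diff(history)
        assert (diffs >= -1e-6).all()

    def test_shift_recovery_two_viewings(self):
        # viewing 2's boundaries two TRs earlier; shared patterns, distinct posteriors
        truth = make_ground_truth(4, 32, 12, [0.0, 3.0], noise_sd=0.0, seed=2)
        subs = generate_subject_viewings(truth, 1, mixing="none", seed=3)
        _, posts = fit_event_model(subs[0], 4)
        lab1 = np.argmax(posts[0].gamma, axis=1)
        lab2 = np.argmax(posts[1].gamma, axis=1)
        assert not np.array_equal(lab1, lab2)
        # every boundary in viewing 2 occurs exactly 2 TRs earlier
        b1 = np.flatnonzero(np.diff(lab1)) + 1
        b2 = np.flatnonzero(np.diff(lab2)) + 1
        np.testing.assert_array_equal(b1 - 2, b2)


class TestExpectedEventCurve:
    def test_one_hot_rows(self):
        gamma = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        from eventshift.hmm import EventPosterior

        curve = expected_event_curve(EventPosterior(gamma, 0.0), 1.5)
        np.testing.assert_array_equal(curve.values, [0, 0, 1, 1])

    def test_uniform_rows_three_events(self):
        from eventshift.hmm import EventPosterior

        gamma = np.full((5, 3), 1 / 3)
        curve = expected_event_curve(EventPosterior(gamma, 0.0), 1.5)
        np.testing.assert_allclose(curve.values, 1.0)

    def test_direct_expectation(self):
        from eventshift.hmm import EventPosterior

        curve = expected_event_curve(EventPosterior(np.array([[0.25, 0.75]]), 0.0), 1.5)
        assert curve.values[0] == pytest.approx(0.75)

    def test_invalid_rows_rejected(self):
        from eventshift.hmm import EventPosterior

        with pytest.raises(ValueError):
            expected_event_curve(EventPosterior(np.array([[0.5, 0.2]]), 0.0), 1.5)


class TestSelectNEvents:
    def test_deterministic_given_split_seed(self):
        truth = make_ground_truth(3, 36, 20, [0.0], noise_sd=0.4, seed=5)
        subs = generate_subject_viewings(truth, 4, mixing="none", seed=6)
        series = [s[0] for s in subs]
        k1, ll1 = select_n_events(series, range(2, 6), split_seed=7)
        k2, ll2 = select_n_events(series, range(2, 6), split_seed=7)
        assert k1 == k2
        assert ll1 == ll2

    def test_k_beyond_t_skipped_with_warning(self, caplog):
        truth = make_ground_truth(2, 8, 10, [0.0], noise_sd=0.2, seed=8)
        subs = generate_subject_viewings(truth, 4, mixing="none", seed=9)
        series = [s[0] for s in subs]
        with caplog.at_level("WARNING"):
            _, logliks = select_n_events(series, range(2, 12), split_seed=0)
        assert max(logliks) <= 8
        assert "skipping" in caplog.text
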