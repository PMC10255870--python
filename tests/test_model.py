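"""Counting network: primitives, shapes, training behavior, inference."""

import numpy as np
import pytest
from sklearn.exceptions import NotFittedError

from repcount import (
    CountingRegressor,
    InvalidDataError,
    count_regions,
    fit_on_corpus,
    hard_mask,
    soft_count,
)


def brute_force_regions(mask):
    """Independent oracle: scan maximal runs of ones."""
    runs = 0
    inside = False
    for v in mask:
        if v == 1 and not inside:
            runs += 1
        inside = v == 1
    return runs


def random_step_signal(rng, tau=0.5, margin=0.2):
    """Piecewise-constant signal whose levels stay `margin` away from tau."""
    n_steps = int(rng.integers(1, 8))
    levels = rng.choice([0.1, 0.9], size=n_steps)
    lengths = rng.integers(3, 30, size=n_steps)
    base = np.repeat(levels, lengths)
    sig = base + rng.uniform(-0.05, 0.05, size=base.size)
    return np.where(base < tau, np.minimum(sig, tau - margin), np.maximum(sig, tau + margin))


class TestMaskAndCount:
    def test_hard_mask_examples(self):
        assert list(hard_mask(np.array([0.1, 0.9, 0.6]), 0.5)) == [0, 1, 1]
        assert list(hard_mask(np.array([0.1, 0.2]), 0.5)) == [0, 0]

    def test_hard_mask_matches_elementwise_oracle(self, rng):
        x = rng.uniform(size=300)
        assert np.array_equal(hard_mask(x, 0.5), (x > 0.5).astype(int))

    @pytest.mark.parametrize(
        "mask, expected",
        [([0, 1, 1, 0, 1], 2), ([1, 1, 1], 1), ([0, 0, 0], 0), ([1], 1), ([], 0)],
    )
    def test_count_regions_examples(self, mask, expected):
        assert count_regions(np.array(mask, dtype=int)) == expected

    def test_count_regions_random_vs_brute_force(self, rng):
        for _ in range(200):
            mask = rng.integers(0, 2, size=rng.integers(1, 200))
            assert count_regions(mask) == brute_force_regions(mask)

    def test_count_regions_rejects_non_binary(self):
        with pytest.raises(InvalidDataError):
            count_regions(np.array([0, 2, 1]))

    def test_two_peak_signal_counts_two(self):
        # the canonical illustration: a step signal with two plateaus
        signal = np.concatenate(
            [np.zeros(20), np.ones(30), np.zeros(25), np.ones(40), np.zeros(10)]
        )
        assert count_regions(hard_mask(signal, 0.5)) == 2


class TestSoftCount:
    def test_constant_above_threshold_tends_to_one(self):
        sig = np.full(50, 0.9)
        assert abs(soft_count(sig, 0.5, 1000.0) - 1.0) < 1e-6

    def test_constant_below_threshold_tends_to_zero(self):
        sig = np.full(50, 0.1)
        assert soft_count(sig, 0.5, 1000.0) < 1e-6

    def test_matches_hard_count_at_high_steepness(self, rng):
        for _ in range(100):
            sig = random_step_signal(rng)
            hard = count_regions(hard_mask(sig, 0.5))
            assert abs(soft_count(sig, 0.5, 1000.0) - hard) < 0.01

    def test_gap_shrinks_as_steepness_doubles(self, rng):
        signals = [random_step_signal(rng) for _ in range(50)]
        hards = [count_regions(hard_mask(s, 0.5)) for s in signals]
        gaps = []
        k = 50.0
        while k <= 1600.0:
            gaps.append(
                max(abs(soft_count(s, 0.5, k) - h) for s, h in zip(signals, hards))
            )
            k *= 2.0
        assert all(b <= a + 1e-12 for a, b in zip(gaps, gaps[1:]))

    def test_rejects_non_positive_steepness(self):
        with pytest.raises(ValueError):
            soft_count(np.zeros(3), 0.5, 0.0)


class TestBuildAndShapes:
    def test_variable_length_shape_contract(self):
        est = CountingRegressor(random_state=0).build(60)
        for L in (1, 7, 500):
            sig = est.step_signal(np.zeros((L, 60)))
            assert sig.shape == (L,)

    def test_same_seed_same_initial_parameters(self):
        a = CountingRegressor(random_state=9).build(8)
        b = CountingRegressor(random_state=9).build(8)
        assert all(np.array_equal(a.params_[k], b.params_[k]) for k in a.params_)

    def test_channel_mismatch_raises(self):
        est = CountingRegressor(random_state=0).build(6)
        with pytest.raises(InvalidDataError):
            est.predict([np.zeros((10, 4))])

    def test_parameter_budget_at_full_width(self):
        est = CountingRegressor(random_state=0).build(60)
        assert est.n_parameters_ < 20_000

    def test_zeroed_parameters_predict_zero(self):
        est = CountingRegressor(random_state=0).build(5)
        for key in est.params_:
            est.params_[key][:] = 0.0
        preds = est.predict([np.random.default_rng(0).uniform(size=(40, 5))])
        assert preds[0] == 0

    def test_predict_before_build_raises(self):
        with pytest.raises(NotFittedError):
            CountingRegressor().predict([np.zeros((5, 3))])

    def test_sklearn_param_roundtrip(self):
        est = CountingRegressor(learning_rate=0.01)
        params = est.get_params()
        clone = CountingRegressor(**params)
        assert clone.get_params() == params


class TestFit:
    def test_warmup_loss_decreases_on_toy_corpus(self, small_corpus):
        est = CountingRegressor(random_state=0, warmup_epochs=6, max_epochs=6,
                                tune_threshold=False)
        fit_on_corpus(est, small_corpus)
        losses = est.history_.train_loss
        assert losses[-1] < losses[0]

    def test_same_seed_identical_histories_and_predictions(self, small_corpus):
        runs = []
        for _ in range(2):
            est = CountingRegressor(random_state=3, warmup_epochs=4, max_epochs=8)
            fit_on_corpus(est, small_corpus)
            X, _ = small_corpus.subset("test")
            runs.append((est.history_.train_loss, est.history_.val_loss,
                         est.mask_threshold_, list(est.predict(X))))
        assert runs[0] == runs[1]

    def test_empty_training_set_rejected(self):
        with pytest.raises(Exception):
            CountingRegressor(random_state=0).fit([], [])

    def test_count_labels_must_be_non_negative(self, small_corpus):
        X, y = small_corpus.subset("train")
        with pytest.raises(InvalidDataError):
            CountingRegressor(random_state=0).fit(X, np.full(len(X), -1))

    def test_history_lengths_consistent(self, small_corpus):
        est = CountingRegressor(random_state=1, warmup_epochs=3, max_epochs=6)
        fit_on_corpus(est, small_corpus)
        h = est.history_
        assert len(h.train_loss) == len(h.val_loss) == len(h.steepness)
        assert 0 <= h.best_epoch < len(h)


class TestInference:
    @pytest.fixture(scope="class")
    def built(self):
        est = CountingRegressor(random_state=7).build(4)
        # random but fixed parameters exercise non-trivial signals
        rng = np.random.default_rng(7)
        for key in est.params_:
            est.params_[key] = est.params_[key] + 0.3 * rng.normal(size=est.params_[key].shape)
        return est

    def test_predictions_are_non_negative_integers(self, built, rng):
        X = [rng.uniform(size=(rng.integers(5, 200), 4)) for _ in range(30)]
        preds = built.predict(X)
        assert preds.dtype == np.int64 and (preds >= 0).all()

    def test_batched_equals_single_sequence_processing(self, built, rng):
        X = [rng.uniform(size=(L, 4)) for L in (50, 51, 500, 3, 120)]
        batched = built.predict(X, batch_size=5)
        singly = np.array([built.predict_count(x) for x in X])
        assert np.array_equal(batched, singly)
        sig_b = built.step_signals(X, batch_size=5)
        sig_s = [built.step_signal(x) for x in X]
        assert max(np.abs(a - b).max() for a, b in zip(sig_b, sig_s)) <= 1e-5

    def test_empty_batch(self, built):
        assert list(built.predict([])) == []
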