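"""Top-k influential sub-signal extraction and the global influential set."""

import numpy as np
import pytest

from tsocclude import (
    BlackBoxModel,
    SignalTensor,
    SyntheticSpec,
    TargetData,
    build_influential_set,
    generate_dataset,
    make_black_box,
    mae,
    segment,
    topk_subsignals,
    topk_subsignals_classification,
    window_scores,
)
from .conftest import random_tensor


def brute_force_window_scores(sample, signal_index, model, d):
    """Independent oracle: materialize each occluded tensor separately."""
    h, n = sample.shape
    names = tuple(f"s{j}" for j in range(n))
    y_ref = model(SignalTensor(sample[None], names))[0]
    scores = []
    for a, b in segment(h, d):
        occluded = sample.copy()
        occluded[a:b, signal_index] = 0.0
        y_occ = model(SignalTensor(occluded[None], names))[0]
        scores.append(mae(y_ref, y_occ))
    return np.array(scores)


class TestWindowScores:
    def test_matches_brute_force_on_random_instances(self, rng):
        """Batched scoring agrees with per-window re-computation."""
        for _ in range(50):
            X = random_tensor(rng, s=1, h=int(rng.integers(6, 40)))
            h = X.n_timesteps
            d = int(rng.integers(1, h))
            j = int(rng.integers(0, X.n_signals))
            w = rng.normal(size=X.n_signals)
            model = make_black_box("linear", weights=w)
            got = np.array([s.score for s in window_scores(X.values[0], j, model, d)])
            expected = brute_force_window_scores(X.values[0], j, model, d)
            assert np.allclose(got, expected, atol=1e-12)

    def test_echo_closed_form(self, rng):
        """Echo box: window i scores sum(|x0[window i]|) / h."""
        x = rng.normal(size=(40, 2))
        model = make_black_box("echo", j=0)
        scores = [s.score for s in window_scores(x, 0, model, d=10)]
        for i, (a, b) in enumerate(segment(40, 10)):
            assert scores[i] == pytest.approx(np.abs(x[a:b, 0]).sum() / 40)


class TestTopkSubsignals:
    def test_constant_box_ties_broken_by_window_index(self, rng):
        x = rng.normal(size=(30, 2))
        subs = topk_subsignals(x, 0, make_black_box("constant"), d=10, k=3)
        assert [s.window_index for s in subs] == [0, 1, 2]
        assert all(s.score == 0.0 for s in subs)

    def test_high_energy_window_ranks_first(self):
        x = np.ones((40, 1))
        x[30:40, 0] = 10.0  # window 3 carries the energy
        subs = topk_subsignals(x, 0, make_black_box("echo", j=0), d=10, k=4)
        assert subs[0].window_index == 3
        assert subs[0].score == pytest.approx(10 * 10 / 40)
        assert subs[1].score == pytest.approx(10 / 40)

    def test_original_values_stored(self, rng):
        x = rng.normal(size=(30, 2))
        subs = topk_subsignals(x, 1, make_black_box("echo", j=1), d=10, k=3)
        for s in subs:
            assert np.array_equal(s.values, x[s.start : s.end, 1])

    def test_k_equals_q_returns_full_profile(self, rng):
        x = rng.normal(size=(25, 1))
        subs = topk_subsignals(x, 0, make_black_box("echo", j=0), d=10, k=3)
        assert len(subs) == 3
        assert subs[-1].truncated  # trailing 5-step window flagged
        scores = [s.score for s in subs]
        assert scores == sorted(scores, reverse=True)

    def test_k_out_of_range(self, rng):
        x = rng.normal(size=(20, 1))
        with pytest.raises(ValueError):
            topk_subsignals(x, 0, make_black_box("echo", j=0), d=10, k=3)

    def test_window_gated_dependence_is_localized(self):
        """Only the gate window of the gate signal gets a nonzero score."""
        for seed in range(10):
            X, _ = generate_dataset(SyntheticSpec(s=1, h=100, n=2, seed=seed))
            model = make_black_box("window_gated", j=1, window_index=2, d=25)
            subs = topk_subsignals(X.values[0], 1, model, d=25, k=4)
            assert subs[0].window_index == 2
            assert all(s.score == 0.0 for s in subs[1:])
            other = topk_subsignals(X.values[0], 0, model, d=25, k=4)
            assert all(s.score == 0.0 for s in other)


class TestClassificationVariant:
    @staticmethod
    def _mean_gate_sample(means):
        """One-signal sample whose windows have the given means (d=10)."""
        h = 10 * len(means)
        x = np.zeros((h, 1))
        for i, m in enumerate(means):
            x[10 * i : 10 * (i + 1), 0] = m
        return x

    def test_no_flip_gives_empty_list(self):
        x = self._mean_gate_sample([5.0, 5.0, 5.0])
        model = make_black_box("threshold_classifier", j=0, tau=0.1)
        Y = TargetData(kind="classification", labels=np.array([1]))
        subs = topk_subsignals_classification(x, 0, model, Y, d=10, k=3)
        assert subs == []  # zeroing one window keeps the mean over tau

    def test_only_flipping_windows_are_candidates(self):
        # overall mean 0.5 > tau; only zeroing window 0 pulls it below
        x = self._mean_gate_sample([1.2, 0.15, 0.15])
        model = make_black_box("threshold_classifier", j=0, tau=0.4)
        Y = TargetData(kind="classification", labels=np.array([1]))
        subs = topk_subsignals_classification(x, 0, model, Y, d=10, k=3)
        assert [s.window_index for s in subs] == [0]
        assert subs[0].prediction_changed is True

    def test_candidates_ranked_by_loss_discrepancy(self):
        # both windows 0 and 1 flip; window 0 moves the mean further
        x = self._mean_gate_sample([1.8, 1.0, 0.2])
        model = make_black_box("threshold_classifier", j=0, tau=0.7, sharpness=5.0)
        Y = TargetData(kind="classification", labels=np.array([1]))
        subs = topk_subsignals_classification(x, 0, model, Y, d=10, k=1)
        assert len(subs) == 1
        assert subs[0].window_index == 0


class TestBuildInfluentialSet:
    def test_single_sample_equals_topk(self, rng):
        x = rng.normal(size=(1, 40, 2))
        X = SignalTensor(x, ("a", "b"))
        model = make_black_box("echo", j=0)
        direct = topk_subsignals(x[0], 0, model, d=10, k=2)
        pooled = build_influential_set(X, 0, model, d=10, k=2, n_global=10)
        assert [s.window_index for s in pooled.sub_signals] == [
            s.window_index for s in direct
        ]

    def test_global_merge_order(self):
        """Disjoint per-sample score sets merge into a descending global order."""
        # sample 0 window means (2.0, 1.2); sample 1 (1.6, 0.8): echo scores
        x = np.zeros((2, 20, 1))
        x[0, :10, 0], x[0, 10:, 0] = 2.0, 1.2
        x[1, :10, 0], x[1, 10:, 0] = 1.6, 0.8
        X = SignalTensor(x, ("a",))
        model = make_black_box("echo", j=0)
        result = build_influential_set(X, 0, model, d=10, k=2, n_global=3)
        assert [round(s.score, 10) for s in result.sub_signals] == [1.0, 0.8, 0.6]
        assert [(s.series_index, s.window_index) for s in result.sub_signals] == [
            (0, 0), (1, 0), (0, 1)
        ]

    def test_n_global_larger_than_union(self, small_tensor):
        model = make_black_box("echo", j=0)
        result = build_influential_set(small_tensor, 0, model, d=20, k=2, n_global=1000)
        assert len(result) == small_tensor.n_samples * 2

    def test_empty_union_warns(self, small_tensor):
        model = make_black_box("threshold_classifier", j=0, tau=-1e9)  # never flips
        Y = TargetData(kind="classification",
                       labels=np.ones(small_tensor.n_samples, dtype=int))
        with pytest.warns(UserWarning, match="empty"):
            result = build_influential_set(small_tensor, 0, model, d=20, k=2,
                                           n_global=10, Y=Y)
        assert len(result) == 0
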