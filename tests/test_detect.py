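"""Detector contracts: thresholding, grid optimization, classification."""

import numpy as np
import pytest

import callspace as cs
from callspace.detect import expand_grid


def _session_with_calls(begins, duration=0.15, rate=19000, noise=0.01,
                        seed=0, freq=2500.0):
    rng = np.random.default_rng(seed)
    total = int((max(begins) + duration + 1.0) * rate)
    wave = rng.normal(0.0, noise, total)
    proto = cs.CallPrototype([freq, freq + 400.0], duration)
    for i, b in enumerate(begins):
        call = cs.synthesize_call(proto, rate, seed=seed + i)
        i0 = int(b * rate)
        wave[i0:i0 + call.size] += call
    truth = [cs.CallSelection("s", b, b + duration) for b in begins]
    return wave, truth


class TestEnergyDetect:
    def test_silence_yields_nothing(self):
        assert cs.energy_detect(np.zeros(19000), 19000,
                                cs.DetectorParams()) == []

    def test_single_call_located(self):
        wave, _ = _session_with_calls([1.0])
        sels = cs.energy_detect(wave, 19000, cs.DetectorParams())
        assert len(sels) == 1
        assert abs(sels[0].begin - 1.0) < 0.02
        assert abs(sels[0].duration - 0.15) < 0.04

    def test_gap_below_hold_time_merges(self):
        rate = 19000
        proto = cs.CallPrototype([2500.0, 2500.0], 0.1)
        call = cs.synthesize_call(proto, rate)
        gap = np.zeros(int(0.01 * rate))  # below the 20 ms hold time
        wave = np.concatenate([np.zeros(rate), call, gap, call, np.zeros(rate)])
        params = cs.DetectorParams(hold_time=0.02, max_duration=0.5)
        sels = cs.energy_detect(wave, rate, params)
        assert len(sels) == 1

    def test_gain_invariance(self):
        wave, _ = _session_with_calls([0.5, 1.5, 2.7])
        params = cs.DetectorParams()
        a = cs.energy_detect(wave, 19000, params)
        b = cs.energy_detect(wave * 7.3, 19000, params)
        assert [(s.begin, s.end) for s in a] == [(s.begin, s.end) for s in b]

    def test_selections_sorted_nonoverlapping(self):
        wave, _ = _session_with_calls([0.5, 1.2, 2.0, 3.3])
        sels = cs.energy_detect(wave, 19000, cs.DetectorParams())
        for s, t in zip(sels, sels[1:]):
            assert s.end <= t.begin

    def test_duration_bounds_discard(self):
        wave, _ = _session_with_calls([1.0])
        params = cs.DetectorParams(min_duration=10.0, max_duration=11.0)
        assert cs.energy_detect(wave, 19000, params) == []


class TestOptimizeDetector:
    def test_perfect_setting_reaches_f1(self):
        wave, truth = _session_with_calls([0.5, 1.5, 2.5, 3.5], noise=0.005)
        grid = {
            "amplitude_threshold": [0.05, 0.1, 0.9],
            "min_duration": [0.05],
            "max_duration": [0.5],
            "hold_time": [0.02],
        }
        best, diag, _ = cs.optimize_detector(wave, 19000, truth, grid)
        assert diag.f_score == 1.0

    def test_absurd_setting_scores_zero(self):
        wave, truth = _session_with_calls([1.0])
        grid = [cs.DetectorParams(min_duration=10.0, max_duration=11.0)]
        _, diag, _ = cs.optimize_detector(wave, 19000, truth, grid)
        assert diag.recall == 0.0
        assert diag.f_score == 0.0

    def test_argmax_matches_brute_force(self):
        """The returned grid point equals an independent re-evaluation of
        every candidate."""
        wave, truth = _session_with_calls([0.5, 1.4, 2.2], noise=0.05, seed=4)
        grid = expand_grid({
            "amplitude_threshold": [0.05, 0.2, 0.6],
            "min_duration": [0.03, 0.08],
            "max_duration": [0.5],
            "hold_time": [0.02],
        })
        best, best_diag, table = cs.optimize_detector(wave, 19000, truth, grid)
        # brute force: recompute every f-score from scratch
        scored = []
        for params in grid:
            diag = cs.match_detections(
                cs.energy_detect(wave, 19000, params), truth
            )
            scored.append((diag.f_score, diag.recall,
                           -params.amplitude_threshold, params))
        expected = max(scored, key=lambda s: s[:3])[3]
        assert best == expected
        assert best_diag.f_score == max(s[0] for s in scored)

    def test_empty_truth_rejected(self):
        wave, _ = _session_with_calls([1.0])
        with pytest.raises(ValueError, match="truth"):
            cs.optimize_detector(wave, 19000, [], [cs.DetectorParams()])


class TestDiagnostics:
    def test_f_score_identity(self):
        d = cs.DetectionDiagnostics(true_positives=8, false_positives=2,
                                    false_negatives=4)
        p, r = d.precision, d.recall
        assert d.f_score == pytest.approx(2 * p * r / (p + r))
        assert 0 <= d.recall <= 1 and 0 <= d.precision <= 1


class TestClassifier:
    @staticmethod
    def _two_gaussians(n_train=500, n_test=200, sep=5.0, dim=6, seed=0):
        rng = np.random.default_rng(seed)
        sig = rng.normal(0.0, 1.0, (n_train, dim))
        noi = rng.normal(sep, 1.0, (n_train, dim))
        X = np.vstack([sig, noi])
        y = np.array(["signal"] * n_train + ["noise"] * n_train)
        Xt = np.vstack([
            rng.normal(0.0, 1.0, (n_test // 2, dim)),
            rng.normal(sep, 1.0, (n_test // 2, dim)),
        ])
        yt = np.array(["signal"] * (n_test // 2) + ["noise"] * (n_test // 2))
        return X, y, Xt, yt

    def test_well_separated_accuracy(self):
        X, y, Xt, yt = self._two_gaussians()
        pred, proba = cs.classify_selections(X, y, Xt, seed=0)
        assert (pred == yt).mean() >= 0.99
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_training_point_recovers_own_label(self):
        X, y, _, _ = self._two_gaussians(n_train=50)
        pred, _ = cs.classify_selections(X, y, X[:1], seed=0)
        assert pred[0] == "signal"

    def test_single_class_training_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="single class"):
            cs.classify_selections(X, ["signal"] * 10, X)

    def test_deterministic_given_seed(self):
        X, y, Xt, _ = self._two_gaussians(sep=1.0)
        p1, pr1 = cs.classify_selections(X, y, Xt, seed=3)
        p2, pr2 = cs.classify_selections(X, y, Xt, seed=3)
        assert np.array_equal(p1, p2)
        assert pr1.equals(pr2)
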