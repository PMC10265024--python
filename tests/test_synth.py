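"""Generator contracts: call synthesis, flock dynamics, social data."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

import callspace as cs
from callspace.synth import (
    SNAPSHOTS_PER_FLOCK,
    _render_session,
    table_calibrated_rates,
)


class TestSynthesizeCall:
    def test_sample_count_is_duration_times_rate(self):
        proto = cs.CallPrototype([2000.0, 2500.0], 0.1)
        wave = cs.synthesize_call(proto, 19000)
        assert wave.size == 1900

    def test_constant_contour_dominant_frequency(self):
        """Per-frame spectral peak of a constant 3 kHz call stays at 3 kHz
        within one frequency-bin width."""
        proto = cs.CallPrototype([3000.0, 3000.0], 0.2, harmonics=1)
        wave = cs.synthesize_call(proto, 19000, noise_level=0.0)
        freqs, _, spec = signal.stft(wave, fs=19000, nperseg=150,
                                     noverlap=75, boundary=None, padded=False)
        bin_width = freqs[1] - freqs[0]
        # skip fade-in/out frames
        dom = freqs[np.argmax(np.abs(spec[:, 2:-2]), axis=0)]
        assert np.all(np.abs(dom - 3000.0) <= bin_width)

    def test_zero_amplitude_renders_silence(self):
        proto = cs.CallPrototype([2000.0, 2500.0], 0.1, amplitude=0.0)
        wave = cs.synthesize_call(proto, 19000, noise_level=0.1, seed=2)
        assert np.all(wave == 0.0)

    def test_nyquist_violation_names_harmonic(self):
        proto = cs.CallPrototype([5000.0, 6000.0], 0.1, harmonics=3)
        with pytest.raises(ValueError, match="18000"):
            cs.synthesize_call(proto, 19000)

    def test_reproducible_given_seed(self):
        proto = cs.CallPrototype([2000.0, 3000.0], 0.1)
        a = cs.synthesize_call(proto, 19000, noise_level=0.05, seed=42)
        b = cs.synthesize_call(proto, 19000, noise_level=0.05, seed=42)
        assert np.array_equal(a, b)


class TestFlockDynamics:
    def test_no_dynamics_keeps_contours_fixed(self, flock_profiles):
        from dataclasses import replace

        static = [
            cs.IndividualProfile(p.individual_id, p.age_class,
                                 p.repertoire, 0.0, 0.0, p.call_rate)
            for p in flock_profiles
        ]
        sim = cs.simulate_flock_calls(static, blocks=5, calls_per_block=0,
                                      seed=1)
        for bid in sim.prototypes_by_block[1]:
            first = sim.prototypes_by_block[1][bid]
            last = sim.prototypes_by_block[5][bid]
            for a, b in zip(first, last):
                assert a.contour_anchor_freqs == b.contour_anchor_freqs

    def test_convergence_shrinks_contour_distance(self, flock_profiles):
        sim = cs.simulate_flock_calls(flock_profiles, blocks=5,
                                      calls_per_block=0, seed=1)
        by_block = sim.truth.groupby("block")["mean_contour_distance"].mean()
        diffs = np.diff(by_block.to_numpy())
        assert np.all(diffs < 0)

    def test_age_preset_direction(self):
        """Older birds: shorter calls, higher frequencies, shallower FM."""
        gen = np.random.default_rng(0)
        young = [cs.make_profile(f"Y{i}", "young", gen) for i in range(40)]
        old = [cs.make_profile(f"O{i}", "old", gen) for i in range(40)]

        def stats(profiles):
            durs = [p.duration for pr in profiles for p in pr.repertoire]
            freqs = [np.mean(p.contour_anchor_freqs)
                     for pr in profiles for p in pr.repertoire]
            fm = [np.ptp(p.contour_anchor_freqs)
                  for pr in profiles for p in pr.repertoire]
            return np.mean(durs), np.mean(freqs), np.mean(fm)

        ydur, yfreq, yfm = stats(young)
        odur, ofreq, ofm = stats(old)
        assert odur < ydur
        assert ofreq > yfreq
        assert ofm < yfm

    def test_truth_selections_tile_call_samples(self):
        """Ground-truth begin/end times land exactly on call sample bounds."""
        rng = np.random.default_rng(3)
        protos = [cs.CallPrototype([2000.0, 2600.0], 0.1)]
        waves = [cs.synthesize_call(protos[0], 19000, seed=i) for i in range(5)]
        session, sels = _render_session(waves, 19000, 0.2, rng, "s")
        assert len(sels) == 5
        for sel, wave in zip(sels, waves):
            i0 = int(round(sel.begin * 19000))
            i1 = int(round(sel.end * 19000))
            assert i1 - i0 == wave.size
            assert np.array_equal(session[i0:i1], wave)
            # silence immediately outside the annotation
            assert session[i0 - 1] == 0.0


class TestInteractions:
    def test_zero_rates_empty_log(self):
        ev = cs.simulate_interactions(list("ABCD"), 0.0, 0.0, sessions=5)
        assert len(ev) == 0

    def test_self_dyad_rejected(self):
        with pytest.raises(ValueError, match="self-dyad"):
            cs.simulate_interactions(list("ABCD"), {("A", "A"): 1.0}, 0.0)

    def test_monte_carlo_mean_matches_rate(self):
        """A dyad with rate 5/session averages ~5 events per session."""
        total = 0
        n_sessions = 40
        for rep in range(25):
            ev = cs.simulate_interactions(
                ["A", "B", "C", "D"], {("A", "B"): 5.0}, 0.0,
                sessions=n_sessions, seed=rep,
            )
            total += len(ev)
        mean_per_session = total / (25 * n_sessions)
        assert mean_per_session == pytest.approx(5.0, rel=0.05)

    def test_events_are_typed_and_undirected_pairs(self):
        ev = cs.simulate_interactions(list("ABCD"), 1.0, 1.0, sessions=4,
                                      seed=0)
        assert set(ev["type"]) <= {"affiliative", "agonistic"}
        assert (ev["actor"] != ev["receiver"]).all()


class TestProximity:
    def test_affinity_one_all_close(self):
        snaps = cs.simulate_proximity(list("ABCD"), 1.0, snapshots=20,
                                      absence_prob=0.0, seed=0)
        assert (snaps["distance_cm"] <= 10.0).all()

    def test_default_snapshot_count(self):
        snaps = cs.simulate_proximity(list("ABCD"), 0.5, seed=0)
        assert snaps["snapshot_id"].nunique() == SNAPSHOTS_PER_FLOCK == 88

    def test_monte_carlo_close_proportion(self):
        snaps = cs.simulate_proximity(list("ABCD"), 0.3, snapshots=10_000,
                                      seed=1)
        prop = (snaps["distance_cm"] <= 10.0).mean()
        assert prop == pytest.approx(0.3, abs=0.01)

    def test_absent_birds_give_missing_distances(self):
        snaps = cs.simulate_proximity(list("ABCD"), 0.5, snapshots=500,
                                      absence_prob=0.3, seed=2)
        assert snaps["distance_cm"].isna().mean() > 0.3


class TestCalibratedRates:
    def test_rates_reproduce_printed_totals(self):
        for age, total in (("young", 316), ("old", 116)):
            r = table_calibrated_rates(age)["affiliative"]
            assert r * 6 * 6 * 8 == pytest.approx(total)

    def test_old_affiliative_rate_lower(self):
        young = table_calibrated_rates("young")
        old = table_calibrated_rates("old")
        assert old["affiliative"] < young["affiliative"]
        assert old["agonistic"] > old["affiliative"]


def test_experiment_bit_reproducible(tmp_path):
    cfg = cs.ExperimentConfig(flocks_per_age=1, sessions_per_block=1,
                              call_rate=3, blocks=2, sample_rate=19000)
    e1 = cs.simulate_experiment(cfg, tmp_path / "a", seed=5)
    e2 = cs.simulate_experiment(cfg, tmp_path / "b", seed=5)
    pd.testing.assert_frame_equal(
        e1.events.reset_index(drop=True), e2.events.reset_index(drop=True)
    )
    w1, _ = cs.read_wav(e1.recordings["wav_path"].iloc[0])
    w2, _ = cs.read_wav(e2.recordings["wav_path"].iloc[0])
    assert np.array_equal(w1, w2)
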