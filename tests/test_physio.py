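"""Band power, sleep-wake scoring, microarousals, transitions, spindles."""

import numpy as np
import pytest

from roawake import physio, synth
from roawake.core import Episode, Hypnogram, per_second_accuracy


def sine(freq, fs=1000.0, dur=30.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandPower:
    def test_pure_delta_sine_concentrates_power(self):
        x = sine(2.0)
        _, delta = physio.band_power(x, 1000.0, (0.5, 4.0), 5.0)
        _, total = physio.band_power(x, 1000.0, (0.5, 30.0), 5.0)
        assert (delta / total > 0.95).all()

    def test_white_noise_power_proportional_to_bandwidth(self, rng):
        x = rng.standard_normal(200_000)
        _, p1 = physio.band_power(x, 1000.0, (10.0, 20.0), 10.0)
        _, p2 = physio.band_power(x, 1000.0, (40.0, 60.0), 10.0)
        assert p2.mean() / p1.mean() == pytest.approx(2.0, rel=0.10)

    def test_parseval_scaling(self):
        x = sine(5.0)
        _, p1 = physio.band_power(x, 1000.0, (4.0, 6.0), 5.0)
        _, p2 = physio.band_power(2 * x, 1000.0, (4.0, 6.0), 5.0)
        assert p2.mean() / p1.mean() == pytest.approx(4.0, rel=1e-6)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            physio.band_power(sine(2.0, fs=100.0), 100.0, (40.0, 60.0), 5.0)


class TestNormalizePower:
    def test_nrem_total_power_averages_one(self):
        p = synth.generate_physiology([("quiet", 30.0), ("NREM", 60.0)],
                                      seed=0)
        hyp = Hypnogram([Episode("quiet", 0, 30), Episode("NREM", 30, 90)])
        powers = physio.epoch_band_powers(p.ecog, p.sampling_rate, 1.0)
        norm, ref = physio.normalize_power(powers, hyp, 1.0)
        in_nrem = (np.arange(norm["total"].size) + 0.5) >= 30
        assert norm["total"][in_nrem].mean() == pytest.approx(1.0)
        assert ref > 0

    def test_scale_invariance_of_normalized_traces(self):
        p = synth.generate_physiology([("NREM", 60.0)], seed=1)
        hyp = Hypnogram([Episode("NREM", 0, 60)])
        pw1 = physio.epoch_band_powers(p.ecog, p.sampling_rate, 1.0)
        pw2 = physio.epoch_band_powers(3.0 * p.ecog, p.sampling_rate, 1.0)
        n1, _ = physio.normalize_power(pw1, hyp, 1.0)
        n2, _ = physio.normalize_power(pw2, hyp, 1.0)
        np.testing.assert_allclose(n1["delta"], n2["delta"], rtol=1e-9)

    def test_missing_nrem_requires_reference(self):
        p = synth.generate_physiology([("REM", 30.0)], seed=2)
        hyp = Hypnogram([Episode("REM", 0, 30)])
        powers = physio.epoch_band_powers(p.ecog, p.sampling_rate, 1.0)
        with pytest.raises(ValueError, match="reference"):
            physio.normalize_power(powers, hyp, 1.0)


class TestScoring:
    def test_wake_sublabel_precedence(self):
        wheel = np.array([2.0, 0.0, 0.0])
        snout = np.array([2.0, 2.0, 0.0])
        labels = physio.score_wake(wheel, snout, 1.0, 1.0)
        assert list(labels) == ["locomotion", "whisking", "quiet"]

    @pytest.mark.parametrize("state", ["NREM", "IS", "REM"])
    def test_single_sleep_state_segments(self, state):
        p = synth.generate_physiology(
            [("quiet", 30.0), ("NREM", 40.0), (state, 60.0)], seed=4)
        rec = physio.PhysioRecording(p.ecog, p.emg, p.sampling_rate)
        hyp = physio.score_session(rec, p.wheel, p.snout,
                                   p.motion_sampling_rate)
        mid = hyp.labels(np.array([100.0]))[0]
        assert mid == state

    def test_full_session_recovery(self):
        sched = [("quiet", 40.0), ("locomotion", 30.0), ("whisking", 30.0),
                 ("quiet", 30.0), ("NREM", 90.0), ("IS", 40.0),
                 ("REM", 50.0)]
        accs = []
        for seed in range(3):
            p = synth.generate_physiology(sched, seed=seed)
            rec = physio.PhysioRecording(p.ecog, p.emg, p.sampling_rate)
            hyp = physio.score_session(rec, p.wheel, p.snout,
                                       p.motion_sampling_rate)
            truth = synth.SimulationConfig(state_schedule=sched).hypnogram()
            accs.append(per_second_accuracy(truth, hyp))
        assert min(accs) >= 0.90


class TestMicroarousals:
    def _hyp(self):
        return Hypnogram([Episode("quiet", 0, 10),
                          Episode("NREM", 10, 110)])

    def test_duration_rules(self):
        fs = 30.0
        snout = np.zeros(int(120 * fs))

        def burst(t0, dur):
            snout[int(t0 * fs):int((t0 + dur) * fs)] = 5.0
        burst(20, 1.0)    # valid microarousal
        burst(40, 0.2)    # too short
        burst(60, 5.0)    # too long: candidate awakening
        burst(2, 1.0)     # outside NREM
        events = physio.detect_microarousals(snout, fs, self._hyp(),
                                             threshold=1.0)
        assert len(events) == 1
        assert events[0].start_s == pytest.approx(20.0, abs=0.1)
        assert 0.3 <= events[0].duration_s < 3.0

    def test_count_matches_brute_force_interval_scan(self, rng):
        fs = 30.0
        snout = (rng.random(int(110 * fs)) < 0.02).astype(float) * 3.0
        hyp = self._hyp()
        events = physio.detect_microarousals(snout, fs, hyp, threshold=1.0)
        above = snout > 1.0
        # brute force: count maximal runs with the duration rule in NREM
        runs, start = [], None
        for i, a in enumerate(above):
            if a and start is None:
                start = i
            if not a and start is not None:
                runs.append((start / fs, i / fs))
                start = None
        if start is not None:
            runs.append((start / fs, above.size / fs))
        want = sum(1 for s, e in runs
                   if 0.3 <= e - s < 3.0 and s >= 10 and e <= 110)
        assert len(events) == want


class TestTransitions:
    def test_no_state_change_empty(self):
        hyp = Hypnogram([Episode("NREM", 0, 60)])
        assert physio.detect_transitions(hyp, method="hypnogram") == []

    def test_sws_cycle_counts_and_awakening_flags(self):
        hyp = Hypnogram([Episode("NREM", 0, 60), Episode("IS", 60, 100),
                         Episode("REM", 100, 150),
                         Episode("quiet", 150, 180)])
        trs = physio.detect_transitions(hyp, method="hypnogram")
        assert len(trs) == 3
        assert [t.awakening for t in trs] == [False, False, True]

    def test_desynchronization_refines_awakening_onset(self):
        # delta-dominant ECoG whose delta collapses 0.5 s before the scored
        # boundary: the refined transition lands at the collapse
        fs = 1000.0
        rng = np.random.default_rng(0)
        from scipy.signal import butter, sosfiltfilt
        sos = butter(4, [0.5, 4.0], btype="bandpass", fs=fs, output="sos")
        delta = sosfiltfilt(sos, rng.standard_normal(int(120 * fs)))
        delta /= delta.std()
        ecog = delta.copy()
        cut = int(99.5 * fs)
        ecog[cut:] *= 0.05  # desynchronization
        hyp = Hypnogram([Episode("NREM", 0, 100),
                         Episode("quiet", 100, 120)])
        trs = physio.detect_transitions(hyp, ecog, fs)
        assert trs[0].awakening and trs[0].refined
        # the surrogate locates the collapse to within a window length
        assert trs[0].time_s == pytest.approx(99.5, abs=1.0)


class TestSpindles:
    fs = 1000.0
    #: detection operates within scored IS episodes of an ECoG that
    #: contains real spindles (they set the working threshold); probe
    #: bursts are injected early in the IS episode
    episode = (60.0, 180.0)

    def _session_with_probe(self, freq, dur, amp, at=65.0, seed=0):
        p = synth.generate_physiology([("NREM", 60.0), ("IS", 120.0)],
                                      spindle_rate_is_per_min=3.0,
                                      seed=seed)
        x = p.ecog.copy()
        m = int(dur * self.fs)
        t = np.arange(m) / self.fs
        i0 = int(at * self.fs)
        x[i0:i0 + m] += amp * np.hanning(m) * np.sin(2 * np.pi * freq * t)
        return x, p.spindle_truth

    def _probe_hits(self, sp, truth, at=65.0, dur=2.0):
        near_truth = lambda t: any(abs(0.5 * (a + b) - t) < 3
                                   for a, b in truth)
        return [s for s in sp if at - 1 < s.peak_time_s < at + dur + 1
                and not near_truth(s.peak_time_s)]

    def test_single_in_band_burst_detected_with_width(self):
        x, truth = self._session_with_probe(13.0, 1.0, amp=6.0)
        sp = physio.detect_spindles(x, self.fs, episodes=[self.episode])
        hits = self._probe_hits(sp, truth, dur=1.0)
        assert len(hits) == 1
        assert 0.5 <= hits[0].width_s <= 5.0
        assert abs(hits[0].peak_time_s - 65.5) < 0.4

    def test_brief_sigma_transient_discarded_by_width_rule(self):
        # a 0.3 s moderate burst crosses the threshold only briefly:
        # width at threshold < 0.5 s
        x, truth = self._session_with_probe(13.0, 0.3, amp=3.0)
        sp = physio.detect_spindles(x, self.fs, episodes=[self.episode])
        assert self._probe_hits(sp, truth, dur=0.3) == []

    def test_out_of_band_burst_not_detected(self):
        # the 2nd-order zero-phase 10-16 Hz Butterworth crushes 25 Hz
        x, truth = self._session_with_probe(25.0, 1.0, amp=6.0)
        sp = physio.detect_spindles(x, self.fs, episodes=[self.episode])
        assert self._probe_hits(sp, truth, dur=1.0) == []

    def test_width_and_band_invariants_on_generator_is(self):
        p = synth.generate_physiology([("IS", 120.0)],
                                      spindle_rate_is_per_min=3.0, seed=3)
        sp = physio.detect_spindles(p.ecog, p.sampling_rate,
                                    episodes=[(0.0, 120.0)])
        assert sp
        for s in sp:
            assert 0.5 <= s.width_s <= 5.0
        rate = physio.spindle_rate(sp, Hypnogram([Episode("IS", 0, 120)]))
        assert rate == pytest.approx(len(sp) / 2.0)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            physio.detect_spindles(np.zeros(int(10 * self.fs)), self.fs,
                                   peak_threshold=0.0)
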