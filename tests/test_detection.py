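"""Three-threshold spike detection: worked examples, oracles, properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import epilfp
from epilfp.detection import SpikeEvent, _enforce_min_dist


def _recording(x, fs=1000.0, label="ctx"):
    meta = epilfp.RecordingMetadata(
        experiment_name="e", animal_id="R01", n_channels=1, fs=fs)
    return epilfp.Recording(metadata=meta, channel_labels=[label],
                            data=np.asarray(x, dtype=float)[np.newaxis, :])


class TestMovingThresholds:
    def test_sixty_percent_of_one_mV_window_is_point_six(self):
        """The canonical worked example: 60% of a 1 mV window maximum."""
        sig = np.zeros(1000)
        sig[400] = 1.0
        thr = epilfp.moving_thresholds(sig, 1000.0, percent=60)
        assert thr.shape == (1,)
        assert thr[0] == pytest.approx(0.6, abs=0.0)

    def test_zero_percent_gives_zero_thresholds(self):
        sig = np.random.default_rng(0).normal(size=3000)
        thr = epilfp.moving_thresholds(sig, 1000.0, percent=0)
        np.testing.assert_array_equal(thr, 0.0)

    def test_hundred_percent_only_window_maxima_reach_threshold(self):
        sig = np.abs(np.random.default_rng(1).normal(size=2000)) + 0.1
        thr = epilfp.moving_thresholds(sig, 1000.0, percent=100)
        for w in range(2):
            win = sig[w * 1000:(w + 1) * 1000]
            assert np.sum(win >= thr[w]) == np.sum(win == win.max())

    def test_windows_partition_with_short_final_window(self):
        sig = np.ones(2500)
        sig[2400] = 2.0  # only in the final (half-length) window
        thr = epilfp.moving_thresholds(sig, 1000.0, percent=50)
        np.testing.assert_allclose(thr, [0.5, 0.5, 1.0])

    def test_rectification_sees_negative_deflections(self):
        sig = np.zeros(1000)
        sig[10] = -2.0
        assert epilfp.moving_thresholds(sig, 1000.0, 50)[0] == pytest.approx(1.0)
        assert epilfp.moving_thresholds(sig, 1000.0, 50, polarity="positive")[0] == 0.0

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            epilfp.moving_thresholds(np.array([]), 1000.0, 50)


def _brute_force_priority(cands, min_dist):
    """Independent O(n^2) application of the keep-largest-first rule."""
    kept = []
    for ev in sorted(cands, key=lambda e: (-e.amplitude, e.time)):
        if all(abs(ev.time - k.time) >= min_dist for k in kept):
            kept.append(ev)
    return sorted(kept, key=lambda e: e.time)


class TestTemporalThreshold:
    def test_worked_greedy_example(self):
        """Candidates at 0.00/0.05/0.20 s; the 0.8 mV one suppresses 0.00 s."""
        cands = [SpikeEvent(0.00, 0.5, 0, 0),
                 SpikeEvent(0.05, 0.8, 50, 0),
                 SpikeEvent(0.20, 0.6, 200, 0)]
        kept = _enforce_min_dist(cands, 0.1)
        assert [e.time for e in kept] == [0.05, 0.20]

    @given(st.lists(st.tuples(st.integers(0, 400), st.integers(1, 1000)),
                    min_size=0, max_size=12))
    @settings(max_examples=200)
    def test_greedy_equals_brute_force_priority_rule(self, raw):
        cands = [SpikeEvent(t / 100.0, a / 100.0, t, 0) for t, a in raw]
        got = _enforce_min_dist(cands, 0.1)
        want = _brute_force_priority(cands, 0.1)
        assert [(e.time, e.amplitude) for e in got] == \
               [(e.time, e.amplitude) for e in want]


class TestDetectSpikes:
    def test_subthreshold_baseline_yields_no_spikes_and_nan_stats(self):
        rec = _recording(np.full(5000, 0.05))
        params = epilfp.DetectionParams(percent=0, fixed_thr=0.1, min_dist=0.1)
        res = epilfp.detect_spikes(rec, "ctx", params)
        assert res.events == []
        assert res.summary.n_spikes == 0
        assert res.summary.firing_rate == 0.0
        assert math.isnan(res.summary.amp_mean) and math.isnan(res.summary.isi_mean)

    def test_planted_impulses_recovered_with_amplitude_priority(self):
        x = np.zeros(1000)
        x[0], x[50], x[200] = 0.5, 0.8, 0.6
        rec = _recording(x)
        params = epilfp.DetectionParams(percent=0, fixed_thr=0.3, min_dist=0.1)
        res = epilfp.detect_spikes(rec, "ctx", params)
        assert [e.time for e in res.events] == [0.05, 0.20]
        assert [e.amplitude for e in res.events] == [0.8, 0.6]

    def test_synthetic_recovery_no_false_positives(self):
        spec = epilfp.SynthSpec(duration=60.0, noise_sd=0.05, spike_rate=0.5,
                                amp=1.0, seed=5)
        rec, truth = epilfp.simulate_channel(spec)
        params = epilfp.DetectionParams(percent=40, fixed_thr=0.1, min_dist=0.1)
        res = epilfp.detect_spikes(rec, "ref", params)
        p, r, f1 = epilfp.score_detection(truth.times("ref"), res.times, tol=0.01)
        assert p == 1.0 and r == 1.0

    def test_negative_polarity_spikes_detected_by_default(self):
        spec = epilfp.SynthSpec(duration=20.0, noise_sd=0.02, seed=9)
        rec, truth = epilfp.simulate_channel(spec)
        flipped = _recording(-rec.data[0], label="ref")
        # min_dist at the generator's refractory gap so every planted
        # spike is individually resolvable
        params = epilfp.DetectionParams(percent=40, fixed_thr=0.1, min_dist=0.05)
        res = epilfp.detect_spikes(flipped, "ref", params)
        _, r, _ = epilfp.score_detection(truth.times("ref"), res.times, tol=0.01)
        assert r == 1.0
        assert all(e.amplitude > 0 for e in res.events)

    def test_window_anchoring_at_t_start(self):
        # one large deflection at 1.25 s; with t_start=0.75 it falls in
        # window 0 of the analysis span, not window 1 of the recording
        x = np.zeros(3000)
        x[1250] = 1.0
        rec = _recording(x)
        params = epilfp.DetectionParams(percent=50, fixed_thr=0.1, min_dist=0.1,
                                        t_start=0.75, t_end=2.75)
        res = epilfp.detect_spikes(rec, "ctx", params)
        assert len(res.events) == 1
        assert res.events[0].window_index == 0
        assert res.events[0].time == pytest.approx(1.25)

    def test_unknown_channel(self, spiky_recording):
        rec, _ = spiky_recording
        with pytest.raises(KeyError):
            epilfp.detect_spikes(rec, "nope", epilfp.DetectionParams())

    def test_span_beyond_recording(self, spiky_recording):
        rec, _ = spiky_recording
        with pytest.raises(ValueError, match="duration"):
            epilfp.detect_spikes(rec, "ref",
                                 epilfp.DetectionParams(t_end=rec.duration + 5))

    def test_events_above_effective_threshold(self, spiky_recording):
        rec, _ = spiky_recording
        params = epilfp.DetectionParams(percent=40, fixed_thr=0.1, min_dist=0.1)
        res = epilfp.detect_spikes(rec, "ref", params)
        assert len(res.events) > 0
        wlen = int(params.win_len * rec.metadata.fs)
        for e in res.events:
            moving = res.thresholds[e.sample_index // wlen]
            assert e.amplitude >= max(moving, params.fixed_thr)


class TestDetectionProperties:
    @given(seed=st.integers(0, 2**20))
    @settings(max_examples=25)
    def test_refractory_invariant_on_random_recordings(self, seed):
        rng = np.random.default_rng(seed)
        spec = epilfp.SynthSpec(
            duration=4.0, noise_sd=float(rng.uniform(0, 0.2)),
            spike_rate=float(rng.uniform(0.2, 2.0)),
            amp=float(rng.uniform(0.3, 2.0)), seed=seed)
        rec, _ = epilfp.simulate_channel(spec)
        min_dist = float(rng.uniform(0.02, 0.3))
        params = epilfp.DetectionParams(
            percent=float(rng.uniform(0, 90)),
            fixed_thr=float(rng.uniform(0, 0.3)), min_dist=min_dist)
        res = epilfp.detect_spikes(rec, "ref", params)
        times = res.times
        if len(times) >= 2:
            assert np.diff(times).min() >= min_dist

    @given(seed=st.integers(0, 2**20))
    @settings(max_examples=15)
    def test_raising_any_threshold_never_adds_spikes(self, seed):
        spec = epilfp.SynthSpec(duration=6.0, noise_sd=0.1, spike_rate=1.0,
                                amp=0.8, amp_jitter_sd=0.3, seed=seed)
        rec, _ = epilfp.simulate_channel(spec)
        base = epilfp.DetectionParams(percent=30, fixed_thr=0.05, min_dist=0.05)
        n0 = epilfp.detect_spikes(rec, "ref", base).summary.n_spikes
        for kw in ({"percent": 60}, {"fixed_thr": 0.2}, {"min_dist": 0.2}):
            params = epilfp.DetectionParams(**{**base.to_dict(), **kw})
            assert epilfp.detect_spikes(rec, "ref", params).summary.n_spikes <= n0


class TestSummarize:
    def test_hand_computed_statistics(self):
        ev = [SpikeEvent(1.0, 0.5, 1000, 0), SpikeEvent(2.0, 1.0, 2000, 2),
              SpikeEvent(4.0, 0.75, 4000, 4)]
        s = epilfp.summarize(ev, 0.0, 10.0)
        assert s.n_spikes == 3
        assert (s.amp_max, s.amp_mean, s.amp_min) == (1.0, 0.75, 0.5)
        assert (s.isi_max, s.isi_mean, s.isi_min) == (2.0, 1.5, 1.0)
        assert s.firing_rate == pytest.approx(0.3)

    def test_single_event_has_undefined_isi(self):
        s = epilfp.summarize([SpikeEvent(1.0, 0.5, 1000, 1)], 0.0, 5.0)
        assert math.isnan(s.isi_mean) and math.isnan(s.isi_max)
        assert s.firing_rate == pytest.approx(0.2)
        assert s.amp_mean == 0.5

    def test_empty_events(self):
        s = epilfp.summarize([], 0.0, 5.0)
        assert s.n_spikes == 0 and s.firing_rate == 0.0
        for v in (s.amp_max, s.amp_mean, s.amp_min, s.isi_max, s.isi_mean, s.isi_min):
            assert math.isnan(v)

    def test_invalid_span(self):
        with pytest.raises(ValueError):
            epilfp.summarize([], 5.0, 5.0)


class TestParamValidation:
    @pytest.mark.parametrize("kw", [
        {"percent": -1}, {"percent": 101}, {"fixed_thr": -0.1},
        {"min_dist": 0.0}, {"win_len": 0.0}, {"polarity": "sideways"},
        {"t_start": 2.0, "t_end": 1.0},
    ])
    def test_rejected(self, kw):
        with pytest.raises(ValueError):
            epilfp.DetectionParams(**kw)
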