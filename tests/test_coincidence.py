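"""Cross-channel spike coincidence: matching rule, percent, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import epilfp
from epilfp.coincidence import UndefinedPercentageError


def _det(times, channel="ctx", t_end=None):
    times = sorted(times)
    ev = [epilfp.SpikeEvent(t, 1.0, int(t * 1000), int(t)) for t in times]
    t_end = t_end if t_end is not None else (times[-1] + 1 if times else 1.0)
    return epilfp.DetectionResult(
        events=ev, params=epilfp.DetectionParams(),
        summary=epilfp.summarize(ev, 0.0, t_end),
        thresholds=np.array([0.0]), channel=channel)


class TestMatchEvents:
    def test_worked_example(self):
        pairs = epilfp.match_events([1.0, 2.0, 3.0], [1.04, 2.5], window=0.1)
        assert pairs == [(1.0, 1.04)]

    def test_identical_trains_self_match(self):
        t = [0.5, 1.5, 2.5, 4.0]
        pairs = epilfp.match_events(t, t, window=0.1)
        assert pairs == [(x, x) for x in t]

    def test_disjoint_trains_no_pairs(self):
        assert epilfp.match_events([1.0, 2.0], [5.0, 6.0], window=0.1) == []

    def test_one_to_one_dense_comparison_train(self):
        # five comparison spikes crowd one reference spike: only one match
        pairs = epilfp.match_events([1.0], [0.96, 0.98, 1.0, 1.02, 1.04], 0.1)
        assert pairs == [(1.0, 1.0)]

    def test_closest_offset_wins(self):
        pairs = epilfp.match_events([1.0, 1.05], [1.04], window=0.1)
        assert pairs == [(1.05, 1.04)]

    def test_tie_goes_to_earlier_reference(self):
        # 0.25 offsets are exactly representable, so this is a true tie
        pairs = epilfp.match_events([1.0, 1.5], [1.25], window=0.3)
        assert pairs == [(1.0, 1.25)]

    @given(
        ref=st.lists(st.integers(0, 60), min_size=0, max_size=10, unique=True),
        comp=st.lists(st.integers(0, 60), min_size=0, max_size=10, unique=True),
        w=st.integers(1, 4),
    )
    @settings(max_examples=200)
    def test_greedy_is_maximal_under_refractory_separation(self, ref, comp, w):
        """When spikes within each train are farther apart than twice the
        window (the refractory regime), each spike has at most one candidate
        partner and greedy matching attains the maximum cardinality."""
        scale = 2 * w + 1  # enforce separation > 2*window
        ref_t = sorted(t * scale / 10.0 for t in ref)
        comp_t = sorted(t * scale / 10.0 for t in comp)
        window = w / 10.0
        pairs = epilfp.match_events(ref_t, comp_t, window)
        # brute-force maximum bipartite matching on the admissible graph
        edges = [(i, j) for i, r in enumerate(ref_t)
                 for j, c in enumerate(comp_t) if abs(r - c) <= window]

        def best(k, used):
            if k == len(edges):
                return 0
            i, j = edges[k]
            skip = best(k + 1, used)
            if i not in used and ~j not in used:
                return max(skip, 1 + best(k + 1, used | {i, ~j}))
            return skip

        assert len(pairs) == best(0, frozenset())
        for r, c in pairs:
            assert abs(r - c) <= window

    def test_known_greedy_limitation_documented(self):
        """Greedy-by-offset is not a maximum matching in general: with
        ref=[0,1], comp=[0.9,1.1], window=1, greedy burns 0.9 on ref 1 and
        leaves ref 0 with nothing, where (0,0.9),(1,1.1) would match both."""
        pairs = epilfp.match_events([0.0, 1.0], [0.9, 1.1], window=1.0)
        assert pairs == [(1.0, 0.9)]  # one pair, not the maximum two


class TestCoincidence:
    def test_channel_versus_itself_is_hundred_percent(self):
        d = _det([0.5, 1.0, 2.0, 3.5], t_end=5.0)
        res = epilfp.coincidence(d, d, epilfp.CoincidenceParams(window=0.1,
                                                                t_end=5.0))
        assert res.percent == 100.0
        assert res.n_matched == res.n_ref == 4

    def test_one_of_three_is_thirty_three_percent(self):
        ref = _det([1.0, 2.0, 3.0], t_end=5.0)
        comp = _det([1.04, 2.5], "hpc", t_end=5.0)
        res = epilfp.coincidence(ref, comp,
                                 epilfp.CoincidenceParams(window=0.1, t_end=5.0))
        assert res.percent == pytest.approx(100.0 / 3.0)
        assert res.pairs == [(1.0, 1.04)]
        assert res.n_ref == 3 and res.n_comp == 2

    def test_span_filtering(self):
        ref = _det([0.5, 2.5, 4.5], t_end=6.0)
        comp = _det([0.5, 2.5, 4.5], "hpc", t_end=6.0)
        res = epilfp.coincidence(
            ref, comp, epilfp.CoincidenceParams(window=0.1, t_start=1.0, t_end=3.0))
        assert res.n_ref == 1 and res.percent == 100.0

    def test_no_reference_spikes_is_undefined_not_zero(self):
        ref = _det([], t_end=5.0)
        comp = _det([1.0], "hpc", t_end=5.0)
        with pytest.raises(UndefinedPercentageError):
            epilfp.coincidence(ref, comp,
                               epilfp.CoincidenceParams(window=0.1, t_end=5.0))

    def test_percent_invariant_to_common_time_shift(self):
        rng = np.random.default_rng(5)
        base = np.sort(rng.uniform(0, 50, 40))
        comp = np.sort(base[: 25] + rng.normal(0, 0.02, 25))
        r1 = epilfp.coincidence(_det(base, t_end=60.0), _det(comp, "h", t_end=60.0),
                                epilfp.CoincidenceParams(window=0.1, t_end=60.0))
        shift = 7.0
        r2 = epilfp.coincidence(_det(base + shift, t_end=70.0),
                                _det(comp + shift, "h", t_end=70.0),
                                epilfp.CoincidenceParams(window=0.1, t_end=70.0))
        assert r1.percent == pytest.approx(r2.percent)

    def test_window_monotonicity(self):
        rng = np.random.default_rng(6)
        ref = np.sort(rng.uniform(0, 30, 25))
        comp = np.sort(rng.uniform(0, 30, 25))
        last = -1
        for w in (0.01, 0.05, 0.1, 0.5):
            res = epilfp.coincidence(_det(ref, t_end=31.0),
                                     _det(comp, "h", t_end=31.0),
                                     epilfp.CoincidenceParams(window=w, t_end=31.0))
            assert res.n_matched >= last
            assert res.n_matched <= min(res.n_ref, res.n_comp)
            last = res.n_matched


class TestSimulatedRecovery:
    def test_detected_coincidence_tracks_planted_probability(self):
        """simulate_pair -> detect both channels -> coincidence recovers the
        planted coincidence probability within binomial sampling error."""
        spec = epilfp.SynthSpec(duration=400.0, coincidence_p=0.6,
                                time_jitter_sd=0.01, seed=17)
        ref, comp, truth = epilfp.simulate_pair(spec)
        params = epilfp.DetectionParams(percent=40, fixed_thr=0.1, min_dist=0.1)
        dr = epilfp.detect_spikes(ref, "ref", params)
        dc = epilfp.detect_spikes(comp, "comp", params)
        res = epilfp.coincidence(dr, dc, epilfp.CoincidenceParams(window=0.1))
        n = res.n_ref
        assert n >= 150
        se = 100 * np.sqrt(0.6 * 0.4 / n)
        assert abs(res.percent - 60.0) <= 3 * se
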