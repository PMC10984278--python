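"""Extension-event detection, synchronicity, bout classification, zones."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from finwake.events import (ExtensionEvent, classify_bout,
                            detect_extension_events, event_position,
                            label_synchronicity)
from finwake.kinematics import Series, body_wave_metrics, com_velocity
from finwake.pipeline import analyze_trial
from finwake.synthetic_data import sample_trial_config, simulate_trial
from tests.conftest import make_track


def series(values, rate=100.0):
    values = np.asarray(values, float)
    return Series(np.arange(len(values)) / rate, values, "L")


def exhaustive_threshold_scan(values, threshold, min_duration, merge_gap):
    """Independent oracle: sample-by-sample scan with explicit merge/discard."""
    above = [bool(np.isfinite(v) and v >= threshold) for v in values]
    runs = []
    start = None
    for i, a in enumerate(above + [False]):
        if a and start is None:
            start = i
        elif not a and start is not None:
            runs.append((start, i))
            start = None
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return [r for r in merged if r[1] - r[0] >= min_duration]


class TestDetectExtensionEvents:
    def test_below_threshold_boundary_no_events(self):
        assert detect_extension_events(series(np.full(100, 0.049))) == []

    def test_at_threshold_counts(self):
        evs = detect_extension_events(series(np.full(100, 0.05)))
        assert len(evs) == 1

    def test_constant_above_spans_whole_series(self):
        evs = detect_extension_events(series(np.full(100, 0.06)))
        assert len(evs) == 1
        e = evs[0]
        assert e.onset == 0.0
        assert e.offset == pytest.approx(1.0)  # first sample after the run
        assert e.t_max == e.onset              # earliest tie

    def test_trapezoid_onset_offset_duration(self):
        v = np.full(300, 0.04)
        v[100:140] = 0.06  # >= 0.05 L exactly for t in [1.00, 1.40)
        evs = detect_extension_events(series(v))
        assert len(evs) == 1
        assert evs[0].onset == pytest.approx(1.00)
        assert evs[0].offset == pytest.approx(1.40)
        assert evs[0].duration == pytest.approx(0.40)

    def test_merge_and_min_duration_rules(self):
        v = np.zeros(60)
        v[10:15] = 0.08
        v[16:20] = 0.08   # 1-frame gap < merge_gap 2 -> merged
        v[40:42] = 0.08   # 2 frames < min_duration 3 -> discarded
        evs = detect_extension_events(series(v))
        assert [(e.onset_frame, e.offset_frame) for e in evs] == [(10, 20)]

    def test_nan_frames_never_in_events(self):
        v = np.full(30, 0.2)
        v[10:20] = np.nan
        evs = detect_extension_events(series(v))
        assert [(e.onset_frame, e.offset_frame) for e in evs] == [(0, 10), (20, 30)]

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 120))
        v = rng.uniform(0, 0.12, n)
        v[rng.random(n) < 0.1] = np.nan
        evs = detect_extension_events(series(v))
        expected = exhaustive_threshold_scan(v, 0.05, 3, 2)
        assert [(e.onset_frame, e.offset_frame) for e in evs] == expected

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_lower_threshold_captures_no_fewer_samples(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 0.12, 100)
        def captured(thr):
            evs = detect_extension_events(series(v), threshold=thr)
            return sum(e.offset_frame - e.onset_frame for e in evs)
        assert captured(0.03) >= captured(0.06)


def ev(onset, offset, side="left"):
    return ExtensionEvent(side=side, onset=onset, offset=offset,
                          t_max=onset, peak_extension=0.1,
                          onset_frame=0, offset_frame=1, t_max_frame=0)


class TestSynchronicity:
    def test_identical_intervals_synchronous(self):
        res = label_synchronicity([ev(0, 1)], [ev(0, 1, "right")])
        assert res.left_labels == ["synchronous"]
        assert res.right_labels == ["synchronous"]

    def test_disjoint_intervals_asynchronous(self):
        res = label_synchronicity([ev(0, 1)], [ev(2, 3, "right")])
        assert res.left_labels == ["asynchronous"]
        assert res.right_labels == ["asynchronous"]

    def test_overlap_fraction_of_shorter_event(self):
        # 0.4 s overlap = 40% of the 1.0 s shorter event -> asynchronous
        res = label_synchronicity([ev(0, 1.0)], [ev(0.6, 1.6, "right")])
        assert res.left_labels == ["asynchronous"]
        # 0.6 s overlap = 60% -> synchronous
        res = label_synchronicity([ev(0, 1.0)], [ev(0.4, 1.4, "right")])
        assert res.left_labels == ["synchronous"]
        assert res.pairs == [(0, 0, pytest.approx(0.6))]

    def test_each_event_in_at_most_one_pair(self):
        left = [ev(0, 1.0), ev(1.2, 2.2)]
        right = [ev(0.1, 1.1, "right")]
        res = label_synchronicity(left, right)
        assert len(res.pairs) == 1
        assert res.left_labels == ["synchronous", "asynchronous"]

    def test_overlapping_same_side_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            label_synchronicity([ev(0, 1.0), ev(0.5, 1.5)], [])

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_swapping_sides_preserves_labels(self, seed):
        rng = np.random.default_rng(seed)

        def rand_events(side):
            t = 0.0
            out = []
            for _ in range(rng.integers(0, 4)):
                t += rng.uniform(0.05, 1.0)
                d = rng.uniform(0.1, 1.0)
                out.append(ev(t, t + d, side))
                t += d
            return out

        L, R = rand_events("left"), rand_events("right")
        res = label_synchronicity(L, R)
        swapped = label_synchronicity(R, L)
        assert res.left_labels == swapped.right_labels
        assert res.right_labels == swapped.left_labels
        assert sorted((j, i) for i, j, _ in res.pairs) == \
            sorted((i, j) for i, j, _ in swapped.pairs)


class TestClassifyBout:
    def _analysis(self, behavior, seed):
        cfg = sample_trial_config(behavior, seed=seed)
        track, _, truth = simulate_trial(cfg)
        return analyze_trial(track, None, cfg.meta,
                             shedding_frequency=truth.shedding_freq)

    def test_karman_gait_all_five_flags(self):
        a = self._analysis("karman_gait", 21)
        assert a.bout.label == "karman_gait"
        kg = {k: v for k, v in a.bout.criteria_flags.items() if k.startswith("kg_")}
        assert all(kg.values()) and len(kg) == 5

    def test_braking_all_four_flags(self):
        a = self._analysis("braking", 22)
        assert a.bout.label == "braking"
        br = {k: v for k, v in a.bout.criteria_flags.items() if k.startswith("br_")}
        assert all(br.values()) and len(br) == 4

    def test_still_is_other(self):
        a = self._analysis("still", 23)
        assert a.bout.label == "other"

    def test_short_bout_rejected(self):
        track = make_track({}, n_frames=30)
        m = body_wave_metrics(make_track({}, n_frames=300), 21.7)
        fwd, _ = com_velocity(track)
        with pytest.raises(ValueError, match="bout"):
            classify_bout(m, fwd, 21.7)


class TestEventPosition:
    @pytest.mark.parametrize("snout,zone", [
        ((10.0, 1.0), "suction_zone"),
        ((18.0, -2.0), "wake"),
        ((-5.0, 0.0), "outside"),
        ((10.0, 5.0), "outside"),  # close downstream but too lateral
    ])
    def test_zone_labels(self, snout, zone):
        track = make_track({"midline_1": np.array(snout)}, n_frames=5)
        event = ExtensionEvent(side="left", onset=0.0, offset=0.02, t_max=0.0,
                               peak_extension=0.1, onset_frame=0,
                               offset_frame=3, t_max_frame=0)
        x, y, z = event_position(event, track)
        assert (x, y) == pytest.approx(snout)
        assert z == zone

    def test_t_max_outside_track_rejected(self):
        track = make_track({}, n_frames=5)
        event = ExtensionEvent(side="left", onset=0.0, offset=1.0, t_max=0.5,
                               peak_extension=0.1, onset_frame=0,
                               offset_frame=99, t_max_frame=80)
        with pytest.raises(ValueError):
            event_position(event, track)
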