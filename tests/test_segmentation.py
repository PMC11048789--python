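"""60-s windowing, class assignment and exclusion rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from afhrv.io import BeatStream
from afhrv.segmentation import (RRInterval, Segment, assign_class, derive_rr,
                                exclusion_rules, preprocess_record,
                                range_filter, window_segments)


def _stream(times, labels=None, tags=None):
    times = np.asarray(times, dtype=float)
    labels = labels or ["normal"] * len(times)
    spans = [(float(times[0]), float(times[-1]), tags or "SR")] if not isinstance(tags, list) else tags
    return BeatStream(record_id="t", beat_times=times, beat_labels=labels,
                      rhythm_spans=spans)


def _segment(durations, rhythm="SR", labels=None, classify=True):
    labels = labels or ["normal"] * len(durations)
    t = np.cumsum(durations) / 1000.0
    seg = Segment(record_id="t", window_index=0, window_start=0.0,
                  intervals=[RRInterval(duration=float(d), end_beat_label=lb,
                                        rhythm_tag=rhythm, end_time_s=float(tt))
                             for d, lb, tt in zip(durations, labels, t)])
    return assign_class(seg) if classify else seg


class TestDeriveRR:
    def test_durations_and_attribution(self):
        rr = derive_rr(_stream([0.0, 0.8, 1.6]))
        assert [iv.duration for iv in rr] == [pytest.approx(800.0)] * 2
        assert [iv.end_time_s for iv in rr] == [0.8, 1.6]

    def test_fewer_than_two_beats_gives_empty_list(self):
        assert derive_rr(_stream([0.5])) == []

    def test_random_stream_elementwise(self, rng):
        times = np.cumsum(rng.uniform(0.4, 1.2, size=100))
        rr = derive_rr(_stream(times))
        np.testing.assert_allclose([iv.duration for iv in rr],
                                   np.diff(times) * 1000.0)


class TestWindowing:
    def test_120s_of_metronome_beats_gives_two_full_windows(self):
        rr = derive_rr(_stream(np.arange(0.0, 121.0)))  # 1000 ms beats
        segs = window_segments(rr)
        assert len(segs) == 2
        assert [len(s.intervals) for s in segs] == [60, 60]

    def test_interval_ending_on_boundary_belongs_to_earlier_window(self):
        # windows are (k*60, (k+1)*60]: an interval terminating exactly at
        # 60 s closes the first window
        iv = RRInterval(duration=800.0, end_beat_label="normal",
                        rhythm_tag="SR", end_time_s=60.0)
        segs = window_segments([iv])
        assert len(segs) == 1 and segs[0].window_index == 0

    def test_empty_input(self):
        assert window_segments([]) == []

    def test_partition_conserves_intervals(self, rng):
        times = np.cumsum(rng.uniform(0.3, 2.5, size=400))
        rr = derive_rr(_stream(times))
        segs = window_segments(rr)
        assert sum(len(s.intervals) for s in segs) == len(rr)
        for s in segs:
            for iv in s.intervals:
                assert s.window_start < iv.end_time_s <= s.window_start + 60.0


class TestAssignClass:
    def test_pure_sr(self):
        assert _segment([800] * 75).class_label == "SR"

    def test_pure_af(self):
        assert _segment([700] * 86, rhythm="AF").class_label == "AF"

    def test_ventricular_beat_excludes_af_segment(self):
        labels = ["normal"] * 85 + ["ventricular"]
        seg = _segment([700] * 86, rhythm="AF", labels=labels)
        assert seg.class_label == "excluded"
        assert seg.exclusion_reason == "ventricular_in_af"

    def test_non_normal_beat_breaks_sr_purity(self):
        seg = _segment([800] * 75, labels=["normal"] * 74 + ["atrial"])
        assert seg.class_label == "excluded"

    def test_mixed_rhythm(self):
        seg = _segment([800] * 75, classify=False)
        for iv in seg.intervals[40:]:
            iv.rhythm_tag = "AF"
        assert assign_class(seg).exclusion_reason == "mixed_rhythm"

    def test_other_rhythm(self):
        seg = _segment([800] * 75, rhythm="other")
        assert seg.exclusion_reason == "other_rhythm"


class TestRangeFilter:
    def test_boundaries_inclusive(self):
        seg = _segment([239.0, 240.0, 3000.0, 3001.0], classify=False)
        range_filter(seg)
        assert [iv.valid for iv in seg.intervals] == [False, True, True, False]

    def test_random_flags_equal_threshold_check(self, rng):
        durations = rng.uniform(100.0, 3500.0, size=200)
        seg = _segment(durations, classify=False)
        range_filter(seg)
        expected = [(240.0 <= d <= 3000.0) for d in durations]
        assert [iv.valid for iv in seg.intervals] == expected


class TestExclusionRules:
    def test_single_3500ms_artefact_excludes_segment(self):
        seg = _segment([800] * 73 + [3500.0])
        range_filter(seg)
        exclusion_rules(seg)
        assert seg.exclusion_reason == "excluded_length_gt_3pct"

    def test_exactly_1800ms_excluded_is_retained(self):
        # the excluded-length rule is a strict ">": 1800 ms on the nose stays
        seg = _segment([900.0, 900.0] + [800.0] * 73)
        for iv in seg.intervals[:2]:
            iv.valid = False
        exclusion_rules(seg)
        assert seg.class_label == "SR"

    def test_short_retained_length_discarded(self):
        seg = _segment([1000.0] * 57)
        range_filter(seg)
        exclusion_rules(seg)
        assert seg.exclusion_reason == "retained_lt_58s"

    def test_full_minute_retained(self):
        seg = _segment([1000.0] * 60)
        range_filter(seg)
        exclusion_rules(seg)
        assert seg.class_label == "SR"


class TestPreprocessRecord:
    def test_pure_sr_record(self):
        times = np.arange(0.0, 601.0, 0.8046875)  # 103/128 s on the grid
        retained, acc = preprocess_record(_stream(times))
        assert acc["retained"] == len(retained)
        assert all(s.class_label == "SR" for s in retained)
        assert acc["retained"] >= 9

    def test_accounting_conserves_windows(self, rng):
        times = np.cumsum(rng.uniform(0.3, 2.0, size=800))
        spans = [(0.0, float(times[-1] / 2), "SR"),
                 (float(times[-1] / 2), float(times[-1]), "AF")]
        stream = _stream(times, tags=spans)
        retained, acc = preprocess_record(stream)
        total = acc.pop("total_windows")
        assert sum(acc.values()) == total

    def test_all_other_rhythm_retains_nothing(self):
        times = np.arange(0.0, 121.0)
        retained, acc = preprocess_record(_stream(times, tags="other"))
        assert retained == []
        assert acc["other_rhythm"] == acc["total_windows"]


@given(st.integers(0, 2**31 - 1))
def test_tightening_range_filter_never_retains_more(seed):
    rng = np.random.default_rng(seed)
    durations = rng.uniform(150.0, 3400.0, size=300)

    def retained_count(lo, hi):
        count = 0
        for start in range(0, 300, 75):
            seg = _segment(durations[start:start + 75])
            range_filter(seg, lo, hi)
            exclusion_rules(seg)
            count += seg.retained
        return count

    assert retained_count(300.0, 2500.0) <= retained_count(240.0, 3000.0)
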