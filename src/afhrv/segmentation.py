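"""60-s RR segmentation and pre-processing rules.

A recording's beat stream is turned into contiguous 60-s windows of RR
intervals.  A window is kept as SR only if every interval originates from
sinus rhythm and terminates in a normal beat; kept as AF only if every
interval is in AF and none terminates in a ventricular beat.  Intervals
outside the 240–3000 ms plausibility range are flagged invalid (never
deleted — exclusion accounting needs them); a window is discarded when the
invalid intervals total more than 1.8 s (3% of the window), or when the
valid intervals total less than 58 s.

Boundary conventions: an interval belongs to the window containing its
terminating beat, windows are ``(k*60, (k+1)*60]`` on the record clock; the
range-filter bounds are inclusive (exactly 240 or 3000 ms is kept); the
excluded-length rule is a strict ``> 1800 ms`` and the retained-length rule
a strict ``< 58 000 ms``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io import BeatStream

EXCLUSION_REASONS = (
    "none", "mixed_rhythm", "ventricular_in_af",
    "excluded_length_gt_3pct", "retained_lt_58s", "other_rhythm", "other",
)

#: defaults of the pre-processing rules
WINDOW_S = 60.0
RR_MIN_MS = 240.0
RR_MAX_MS = 3000.0
EXCLUDED_MAX_MS = 1800.0
RETAINED_MIN_MS = 58_000.0

_EPS = 1e-9  # guards float window arithmetic; beat times live on a 1/128 s grid


@dataclass
class RRInterval:
    """One RR interval, attributed to its terminating beat."""

    duration: float  # ms, > 0
    end_beat_label: str
    rhythm_tag: str
    end_time_s: float
    valid: bool = True


@dataclass
class Segment:
    """One 60-s window of RR intervals with class label and exclusion bookkeeping."""

    record_id: str
    window_index: int
    window_start: float  # s
    intervals: list[RRInterval] = field(default_factory=list)
    class_label: str | None = None  # None until classified; then AF/SR/excluded
    exclusion_reason: str = "none"

    @property
    def durations(self) -> np.ndarray:
        return np.array([iv.duration for iv in self.intervals], dtype=float)

    @property
    def valid_durations(self) -> np.ndarray:
        return np.array([iv.duration for iv in self.intervals if iv.valid], dtype=float)

    @property
    def retained(self) -> bool:
        return self.class_label in ("AF", "SR")


def derive_rr(stream: BeatStream) -> list[RRInterval]:
    """Successive beat-to-beat intervals; empty if fewer than 2 beats."""
    if stream.n_beats < 2:
        return []
    out = []
    for i in range(stream.n_beats - 1):
        t1 = float(stream.beat_times[i + 1])
        out.append(RRInterval(
            duration=(t1 - float(stream.beat_times[i])) * 1000.0,
            end_beat_label=stream.beat_labels[i + 1],
            rhythm_tag=stream.rhythm_at(t1),
            end_time_s=t1,
        ))
    return out


def window_segments(rr: list[RRInterval], record_id: str = "",
                    window_s: float = WINDOW_S) -> list[Segment]:
    """Partition intervals into contiguous windows ``(k*w, (k+1)*w]``.

    Trailing partial windows are produced; the retained-length rule removes
    them downstream.  Every interval lands in exactly one window.
    """
    if not rr:
        return []
    by_index: dict[int, list[RRInterval]] = {}
    for iv in rr:
        k = int(np.floor((iv.end_time_s - _EPS) / window_s))
        k = max(k, 0)
        by_index.setdefault(k, []).append(iv)
    return [
        Segment(record_id=record_id, window_index=k, window_start=k * window_s,
                intervals=by_index.get(k, []))
        for k in range(max(by_index) + 1)
    ]


def assign_class(segment: Segment) -> Segment:
    """Label a window SR, AF or excluded from its rhythm tags and beat labels."""
    tags = {iv.rhythm_tag for iv in segment.intervals}
    labels = [iv.end_beat_label for iv in segment.intervals]
    if not segment.intervals or "other" in tags:
        segment.class_label, segment.exclusion_reason = "excluded", "other_rhythm"
    elif tags == {"SR", "AF"}:
        segment.class_label, segment.exclusion_reason = "excluded", "mixed_rhythm"
    elif tags == {"SR"}:
        if all(lb == "normal" for lb in labels):
            segment.class_label, segment.exclusion_reason = "SR", "none"
        else:
            segment.class_label, segment.exclusion_reason = "excluded", "other"
    else:  # tags == {"AF"}
        if any(lb == "ventricular" for lb in labels):
            segment.class_label, segment.exclusion_reason = "excluded", "ventricular_in_af"
        else:
            segment.class_label, segment.exclusion_reason = "AF", "none"
    return segment


def range_filter(segment: Segment, lo_ms: float = RR_MIN_MS,
                 hi_ms: float = RR_MAX_MS) -> Segment:
    """Flag intervals outside [lo, hi] ms invalid (bounds inclusive, kept)."""
    for iv in segment.intervals:
        iv.valid = lo_ms <= iv.duration <= hi_ms
    return segment


def exclusion_rules(segment: Segment, excluded_max_ms: float = EXCLUDED_MAX_MS,
                    retained_min_ms: float = RETAINED_MIN_MS) -> Segment:
    """Apply the excluded-length (>1.8 s) and retained-length (<58 s) rules."""
    if not segment.retained:
        return segment
    dur = segment.durations
    valid = np.array([iv.valid for iv in segment.intervals], dtype=bool)
    if dur[~valid].sum() > excluded_max_ms:
        segment.class_label, segment.exclusion_reason = "excluded", "excluded_length_gt_3pct"
    elif dur[valid].sum() < retained_min_ms:
        segment.class_label, segment.exclusion_reason = "excluded", "retained_lt_58s"
    return segment


def preprocess_record(
    stream: BeatStream,
    window_s: float = WINDOW_S,
    lo_ms: float = RR_MIN_MS,
    hi_ms: float = RR_MAX_MS,
    excluded_max_ms: float = EXCLUDED_MAX_MS,
    retained_min_ms: float = RETAINED_MIN_MS,
) -> tuple[list[Segment], dict[str, int]]:
    """Full pre-processing chain for one recording.

    Returns the retained segments and an accounting dict whose values sum to
    the total number of windows (key ``retained`` plus one count per
    exclusion reason).
    """
    rr = derive_rr(stream)
    segments = window_segments(rr, record_id=stream.record_id, window_s=window_s)
    counts: Counter[str] = Counter()
    retained: list[Segment] = []
    for seg in segments:
        assign_class(seg)
        range_filter(seg, lo_ms, hi_ms)
        exclusion_rules(seg, excluded_max_ms, retained_min_ms)
        if seg.retained:
            counts["retained"] += 1
            retained.append(seg)
        else:
            counts[seg.exclusion_reason] += 1
    counts["total_windows"] = len(segments)
    return retained, dict(counts)
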