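"""Reading beat/rhythm annotation streams and writing feature tables.

Two input dialects are supported:

* ``fixture`` — a plain CSV with columns ``time_s, beat_label, rhythm_tag``
  using the canonical vocabularies (beat labels ``normal/atrial/ventricular/
  artefact/other``; rhythm tags ``SR/AF/other``).  This is the dialect the
  synthetic generator emits.
* ``wfdb`` — MIT/WFDB binary annotation files (beat annotations plus ``+``
  rhythm-change annotations whose AUX strings follow the ``(AFIB`` / ``(N``
  convention), with the sampling frequency taken from the sibling ``.hea``
  header (128 Hz if absent, the Holter convention).

Rhythm and beat vocabularies are mapped through explicit, overridable
dictionaries; anything unmapped becomes ``other`` and is excluded downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import wfdb_annot
from .errors import ValidationError

log = logging.getLogger(__name__)

BEAT_LABELS = ("normal", "atrial", "ventricular", "artefact", "other")
RHYTHM_TAGS = ("SR", "AF", "other")

#: WFDB beat symbol -> canonical beat label
DEFAULT_BEAT_MAP: dict[str, str] = {
    "N": "normal", "L": "normal", "R": "normal", "e": "normal", "j": "normal",
    "A": "atrial", "a": "atrial", "S": "atrial", "J": "atrial", "n": "atrial",
    "V": "ventricular", "E": "ventricular", "!": "ventricular", "F": "ventricular",
    "~": "artefact", "|": "artefact", "x": "artefact", "Q": "other", "/": "other",
    "f": "other",
}

#: WFDB aux rhythm string -> canonical rhythm tag
DEFAULT_RHYTHM_MAP: dict[str, str] = {
    "(N": "SR", "(NSR": "SR", "(SR": "SR",
    "(AFIB": "AF", "(AF": "AF",
}

FEATURE_TABLE_COLUMNS = [
    "record_id", "window_index", "class_label",
    "pRR30", "pRR3.25", "H", "HAR", "HDR", "HNR",
    "mean_rr", "n_intervals",
]


@dataclass
class BeatStream:
    """Timestamped beats with beat-type and rhythm labels for one recording.

    ``rhythm_spans`` is an ordered, non-overlapping, contiguous list of
    ``(start_s, end_s, tag)`` covering the record extent; a beat at time *t*
    belongs to the span with the largest start <= *t*.
    """

    record_id: str
    beat_times: np.ndarray  # seconds from record start, strictly increasing
    beat_labels: list[str]
    rhythm_spans: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if len(self.beat_times) != len(self.beat_labels):
            raise ValidationError("beat_times and beat_labels lengths differ")
        if len(self.beat_times) > 1:
            bad = np.flatnonzero(np.diff(self.beat_times) <= 0)
            if bad.size:
                raise ValidationError(
                    f"beat times not strictly increasing at index {bad[0] + 1}"
                )

    @property
    def n_beats(self) -> int:
        return len(self.beat_times)

    def rhythm_at(self, t: float) -> str:
        """Rhythm tag of the span containing time *t* (``other`` outside)."""
        if not self.rhythm_spans:
            return "other"
        starts = np.array([s for s, _, _ in self.rhythm_spans])
        k = int(np.searchsorted(starts, t, side="right")) - 1
        if k < 0:
            return "other"
        return self.rhythm_spans[k][2]


def _spans_from_tags(times: np.ndarray, tags: list[str]) -> list[tuple[float, float, str]]:
    """Group per-beat rhythm tags into contiguous spans over the record extent."""
    spans: list[tuple[float, float, str]] = []
    start = times[0]
    cur = tags[0]
    for t, tag in zip(times[1:], tags[1:]):
        if tag != cur:
            spans.append((float(start), float(t), cur))
            start, cur = t, tag
    spans.append((float(start), float(times[-1]), cur))
    return spans


def read_beat_annotations(
    path: str | Path,
    dialect: str = "fixture",
    rhythm_map: dict[str, str] | None = None,
    beat_map: dict[str, str] | None = None,
) -> BeatStream:
    """Read one recording's beat/rhythm annotations into a :class:`BeatStream`."""
    path = Path(path)
    if dialect == "fixture":
        return _read_fixture(path)
    if dialect == "wfdb":
        return _read_wfdb(path, rhythm_map or DEFAULT_RHYTHM_MAP,
                          beat_map or DEFAULT_BEAT_MAP)
    raise ValidationError(f"unknown dialect {dialect!r}")


def _read_fixture(path: Path) -> BeatStream:
    df = pd.read_csv(path)
    required = {"time_s", "beat_label", "rhythm_tag"}
    if not required.issubset(df.columns):
        raise ValidationError(f"fixture file {path} missing columns {required - set(df.columns)}")
    times = df["time_s"].to_numpy(dtype=float)
    if len(times) > 1:
        bad = np.flatnonzero(np.diff(times) <= 0)
        if bad.size:
            raise ValidationError(f"beat times not strictly increasing at index {bad[0] + 1}")
    labels = [lb if lb in BEAT_LABELS else "other" for lb in df["beat_label"]]
    tags = [tg if tg in RHYTHM_TAGS else "other" for tg in df["rhythm_tag"]]
    spans = _spans_from_tags(times, tags) if len(times) else []
    return BeatStream(record_id=path.stem, beat_times=times,
                      beat_labels=labels, rhythm_spans=spans)


def _read_wfdb(path: Path, rhythm_map: dict[str, str],
               beat_map: dict[str, str]) -> BeatStream:
    anns = wfdb_annot.read_annotations(path)
    fs = wfdb_annot.read_sampling_frequency(path.with_suffix(".hea"))
    times: list[float] = []
    labels: list[str] = []
    boundaries: list[tuple[float, str]] = []  # (time, tag) rhythm changes
    for a in anns:
        t = a.sample / fs
        if a.symbol == "+":
            tag = rhythm_map.get((a.aux or "").rstrip("\x00"))
            if tag is None:
                log.warning("unknown rhythm string %r at t=%.3f s -> other", a.aux, t)
                tag = "other"
            boundaries.append((t, tag))
        else:
            times.append(t)
            labels.append(beat_map.get(a.symbol, "other"))
    times_arr = np.asarray(times)
    if len(times_arr) > 1:
        bad = np.flatnonzero(np.diff(times_arr) <= 0)
        if bad.size:
            raise ValidationError(f"beat times not strictly increasing at index {bad[0] + 1}")
    spans: list[tuple[float, float, str]] = []
    if len(times_arr):
        first, last = float(times_arr[0]), float(times_arr[-1])
        if not boundaries or boundaries[0][0] > first:
            # beats before the first rhythm annotation carry no rhythm
            boundaries.insert(0, (first, "other"))
        for i, (t0, tag) in enumerate(boundaries):
            t1 = boundaries[i + 1][0] if i + 1 < len(boundaries) else last
            spans.append((t0, t1, tag))
    return BeatStream(record_id=path.stem, beat_times=times_arr,
                      beat_labels=labels, rhythm_spans=spans)


def write_fixture(stream: BeatStream, path: str | Path) -> None:
    """Write a BeatStream in the fixture CSV dialect (per-beat rhythm tags)."""
    tags = [stream.rhythm_at(t) for t in stream.beat_times]
    df = pd.DataFrame({
        "time_s": stream.beat_times,
        "beat_label": stream.beat_labels,
        "rhythm_tag": tags,
    })
    df.to_csv(path, index=False, float_format="%.6f")


def write_wfdb(stream: BeatStream, path: str | Path, fs: float = 128.0) -> None:
    """Write a BeatStream as a WFDB annotation file + minimal header."""
    inv_beat = {"normal": "N", "atrial": "A", "ventricular": "V",
                "artefact": "|", "other": "Q"}
    inv_rhythm = {"SR": "(N", "AF": "(AFIB", "other": "(OTHER"}
    anns: list[wfdb_annot.Annotation] = []
    for start, _, tag in stream.rhythm_spans:
        anns.append(wfdb_annot.Annotation(sample=int(round(start * fs)),
                                          symbol="+", aux=inv_rhythm[tag]))
    for t, lb in zip(stream.beat_times, stream.beat_labels):
        anns.append(wfdb_annot.Annotation(sample=int(round(t * fs)),
                                          symbol=inv_beat[lb]))
    # rhythm change sorts before the beat it coincides with
    anns.sort(key=lambda a: (a.sample, a.symbol != "+"))
    path = Path(path)
    wfdb_annot.write_annotations(path, anns)
    wfdb_annot.write_header(path.with_suffix(".hea"), path.stem, fs)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-segment feature table as CSV (deterministic column order)."""
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"feature table missing columns {missing}")
    table = table[FEATURE_TABLE_COLUMNS]
    table.to_csv(path, index=False, float_format="%.8g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
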