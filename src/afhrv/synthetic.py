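"""Synthetic 60-s RR tachograms with SR and AF structure.

The generator emulates what the analysis actually consumes — the shape of
the per-segment feature distributions — not cardiac electrophysiology:

* Sinus rhythm: an AR(1) drift around a long mean (gradual, autocorrelated
  changes driven by autonomic modulation) plus a sinusoidal respiratory
  component, quantized to the 1/128 s Holter sampling grid.  Quantization is
  the sole source of zero differences, so neutral runs appear at realistic
  rates.
* Atrial fibrillation: i.i.d. draws around a shorter mean with a large SD,
  truncated to the physiologic (240, 3000) ms range and quantized.  Large
  near-random successive changes; exact repeats are rare, so neutral runs
  are scarce.

Defaults live in ``generator_defaults.yaml`` (versioned; calibration script
under ``scripts/``).  All generation is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .io import BeatStream, _spans_from_tags
from .segmentation import (RRInterval, Segment, assign_class, exclusion_rules,
                           range_filter)

_MS = 1000.0


def _load_defaults() -> dict:
    text = resources.files("afhrv").joinpath("generator_defaults.yaml").read_text()
    return yaml.safe_load(text)


_DEFAULTS = _load_defaults()


@dataclass(frozen=True)
class SRGenParams:
    mean_rr: float = _DEFAULTS["sr"]["mean_rr"]
    ar_coefficient: float = _DEFAULTS["sr"]["ar_coefficient"]
    innovation_sd: float = _DEFAULTS["sr"]["innovation_sd"]
    rsa_amplitude: float = _DEFAULTS["sr"]["rsa_amplitude"]
    rsa_period: float = _DEFAULTS["sr"]["rsa_period"]
    grid: float = _DEFAULTS["sr"]["grid"]

    def __post_init__(self):
        if not 0.0 < self.ar_coefficient < 1.0:
            raise ValidationError("ar_coefficient must be in (0, 1)")
        if self.mean_rr <= 0 or self.grid <= 0 or self.rsa_period <= 0:
            raise ValidationError("mean_rr, grid and rsa_period must be positive")
        if self.innovation_sd < 0 or self.rsa_amplitude < 0:
            raise ValidationError("innovation_sd and rsa_amplitude must be >= 0")


@dataclass(frozen=True)
class AFGenParams:
    mean_rr: float = _DEFAULTS["af"]["mean_rr"]
    sd: float = _DEFAULTS["af"]["sd"]
    correlation: float = _DEFAULTS["af"]["correlation"]
    grid: float = _DEFAULTS["af"]["grid"]

    def __post_init__(self):
        if self.mean_rr <= 0 or self.grid <= 0:
            raise ValidationError("mean_rr and grid must be positive")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if not 0.0 <= self.correlation < 1.0:
            raise ValidationError("correlation must be in [0, 1)")


@dataclass(frozen=True)
class DatasetSpec:
    n_sr: int
    n_af: int
    seed: int = 0
    artifact_rate: float = 0.0  # fraction of intervals replaced by out-of-range values
    segments_per_record: int = 10

    def __post_init__(self):
        if self.n_sr < 1 or self.n_af < 1:
            raise ValidationError("need at least one segment per class")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValidationError("artifact_rate must be in [0, 1]")


def _quantize(rr_ms: np.ndarray, grid_s: float) -> np.ndarray:
    step = grid_s * _MS
    return np.maximum(np.round(rr_ms / step), 1.0) * step


def gen_sr_rr(params: SRGenParams = SRGenParams(), duration: float = 60.0,
              seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sinus-rhythm RR series (ms) covering at least *duration* seconds."""
    if duration < 1.0:
        raise ValidationError("duration must be >= 1 s")
    rng = np.random.default_rng(seed)
    phi, innov = params.ar_coefficient, params.innovation_sd
    # stationary start for the AR(1) component
    x = rng.normal(0.0, innov / np.sqrt(1.0 - phi * phi)) if innov > 0 else 0.0
    out: list[float] = []
    t = 0.0  # cumulative time (s) drives the respiratory phase
    target = duration * _MS
    total = 0.0
    while total < target:
        rsa = params.rsa_amplitude * np.sin(2.0 * np.pi * t / params.rsa_period)
        rr = float(_quantize(np.array([params.mean_rr + x + rsa]), params.grid)[0])
        out.append(rr)
        total += rr
        t += rr / _MS
        x = phi * x + (rng.normal(0.0, innov) if innov > 0 else 0.0)
    return np.array(out)


def gen_af_rr(params: AFGenParams = AFGenParams(), duration: float = 60.0,
              seed: int | np.random.Generator = 0) -> np.ndarray:
    """AF RR series (ms): truncated i.i.d. (or AR(1) if correlation > 0)."""
    if duration < 1.0:
        raise ValidationError("duration must be >= 1 s")
    rng = np.random.default_rng(seed)
    out: list[float] = []
    total = 0.0
    target = duration * _MS
    prev_dev = 0.0
    rho = params.correlation
    innov_sd = params.sd * np.sqrt(1.0 - rho * rho)
    while total < target:
        dev = rho * prev_dev + (rng.normal(0.0, innov_sd) if params.sd > 0 else 0.0)
        rr = params.mean_rr + dev
        while not (240.0 < rr < 3000.0):  # truncation by redraw
            dev = rng.normal(0.0, params.sd) if params.sd > 0 else 0.0
            rr = params.mean_rr + dev
        prev_dev = dev
        rr = float(_quantize(np.array([rr]), params.grid)[0])
        out.append(rr)
        total += rr
    return np.array(out)


def _segment_from_rr(rr: np.ndarray, rhythm: str, record_id: str,
                     window_index: int) -> Segment:
    t = np.cumsum(rr) / _MS
    intervals = [RRInterval(duration=float(d), end_beat_label="normal",
                            rhythm_tag=rhythm, end_time_s=float(tt))
                 for d, tt in zip(rr, t)]
    return Segment(record_id=record_id, window_index=window_index,
                   window_start=0.0, intervals=intervals)


def gen_labelled_dataset(
    spec: DatasetSpec,
    sr: SRGenParams = SRGenParams(),
    af: AFGenParams = AFGenParams(),
) -> tuple[list[Segment], pd.DataFrame]:
    """Labelled synthetic segments plus the retained segments' feature rows.

    Segments are grouped into pure-class pseudo-recordings of
    ``segments_per_record`` segments each so the grouped train/test split is
    exercisable.  With ``artifact_rate > 0`` some intervals are replaced by
    3500 ms outliers, which drives the exclusion rules.
    """
    from .pipeline import extract_features  # local import avoids a cycle

    root = np.random.default_rng(spec.seed)
    segments: list[Segment] = []
    for rhythm, count, params, gen in (("SR", spec.n_sr, sr, gen_sr_rr),
                                       ("AF", spec.n_af, af, gen_af_rr)):
        for i in range(count):
            rr = gen(params, 60.0, root.spawn(1)[0])
            if spec.artifact_rate > 0:
                hit = root.random(rr.size) < spec.artifact_rate
                rr = np.where(hit, 3500.0, rr)
            rec = f"{rhythm.lower()}_rec{i // spec.segments_per_record:04d}"
            seg = _segment_from_rr(rr, rhythm, rec, i % spec.segments_per_record)
            assign_class(seg)
            range_filter(seg)
            exclusion_rules(seg)
            segments.append(seg)
    table = extract_features([s for s in segments if s.retained])
    return segments, table


def gen_multirhythm_record(
    layout: list[tuple[str, float]],
    seed: int = 0,
    sr: SRGenParams = SRGenParams(),
    af: AFGenParams = AFGenParams(),
    record_id: str = "synthetic",
) -> BeatStream:
    """A whole recording of concatenated rhythm blocks, e.g. [("SR", 90), ("AF", 90)].

    Rhythm spans follow the block boundaries; windows straddling a boundary
    become mixed-rhythm exclusions downstream.  Blocks tagged ``other`` use
    the SR generator but carry the ``other`` rhythm tag.
    """
    if not layout:
        raise ValidationError("layout must be non-empty")
    root = np.random.default_rng(seed)
    rr_all: list[np.ndarray] = []
    tags: list[str] = []
    for rhythm, dur in layout:
        child = root.spawn(1)[0]
        rr = gen_af_rr(af, dur, child) if rhythm == "AF" else gen_sr_rr(sr, dur, child)
        rr_all.append(rr)
        tags.extend([rhythm if rhythm in ("SR", "AF") else "other"] * rr.size)
    rr_cat = np.concatenate(rr_all)
    beat_times = np.concatenate(([0.0], np.cumsum(rr_cat) / _MS))
    # per-beat tags: the first beat inherits the first block's tag
    beat_tags = [tags[0]] + tags
    spans = _spans_from_tags(beat_times, beat_tags)
    return BeatStream(record_id=record_id, beat_times=beat_times,
                      beat_labels=["normal"] * len(beat_times),
                      rhythm_spans=spans)
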