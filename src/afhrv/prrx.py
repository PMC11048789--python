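"""pRRx and pRRx% successive-difference statistics.

pRRx is the percentage of successive RR-interval differences whose magnitude
is at least x ms (pRR50 with x = 50 ms is the classic HRV index).  pRRx% is
the scale-invariant variant: the threshold is x percent of the *previous*
RR interval of each pair.  Both comparisons are inclusive (>= x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class PRRxResult:
    threshold_kind: str  # "absolute_ms" | "relative_pct"
    threshold_value: float
    percentage: float  # in [0, 100]


def successive_differences(rr) -> np.ndarray:
    """Signed differences delta_i = RR_{i+1} - RR_i (length N-1)."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValidationError("need at least 2 intervals for successive differences")
    return np.diff(rr)


def prrx_ms(rr, x: float = 30.0) -> PRRxResult:
    """Percentage of |delta_i| >= x ms."""
    if x <= 0:
        raise ValidationError("threshold x must be positive")
    deltas = successive_differences(rr)
    pct = 100.0 * np.count_nonzero(np.abs(deltas) >= x) / deltas.size
    return PRRxResult("absolute_ms", x, float(pct))


def prrx_rel(rr, x: float = 3.25) -> PRRxResult:
    """Percentage of |delta_i| >= (x/100) * RR_i, RR_i the earlier interval."""
    if x <= 0:
        raise ValidationError("threshold x must be positive")
    rr = np.asarray(rr, dtype=float)
    deltas = successive_differences(rr)
    thresholds = (x / 100.0) * rr[:-1]
    pct = 100.0 * np.count_nonzero(np.abs(deltas) >= thresholds) / deltas.size
    return PRRxResult("relative_pct", x, float(pct))
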