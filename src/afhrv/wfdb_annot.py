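"""Minimal reader/writer for MIT/WFDB annotation files.

Implements the subset of the annotation binary format needed to work with
Holter beat + rhythm annotations: beat codes, the ``+`` rhythm-change code
with its AUX string (e.g. ``(AFIB``, ``(N``), SKIP for long intervals, and
NUM/SUB/CHN pseudo-annotations (parsed and ignored).  Also reads/writes the
one header line needed to recover the sampling frequency.

The format is a stream of 16-bit little-endian words.  The high 6 bits are
the annotation code, the low 10 bits the time increment in samples since
the previous annotation.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

from .errors import ValidationError

# Pseudo-annotation codes
_SKIP = 59
_NUM = 60
_SUB = 61
_CHN = 62
_AUX = 63

# Subset of the standard WFDB annotation code table (code -> symbol)
CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    28: "+", 31: "!", 34: "e", 35: "n", 37: "x", 38: "f",
}
SYMBOL_TO_CODE = {s: c for c, s in CODE_TO_SYMBOL.items()}


@dataclass
class Annotation:
    sample: int
    symbol: str
    aux: str | None = None


def read_annotations(path: str | Path) -> list[Annotation]:
    """Parse a WFDB annotation file into a list of :class:`Annotation`."""
    data = Path(path).read_bytes()
    anns: list[Annotation] = []
    t = 0
    pending = 0
    i = 0
    n = len(data)
    while i + 1 < n:
        word = struct.unpack_from("<H", data, i)[0]
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if code == 0 and delta == 0:
            break
        if code == _SKIP:
            hi = struct.unpack_from("<h", data, i)[0]
            lo = struct.unpack_from("<H", data, i + 2)[0]
            i += 4
            pending += (hi << 16) | lo
        elif code == _AUX:
            aux = data[i : i + delta].decode("latin-1").rstrip("\x00")
            i += delta + (delta & 1)  # pad to even
            if anns:
                anns[-1].aux = aux
        elif code in (_NUM, _SUB, _CHN):
            pass  # value carried in delta; not needed here
        else:
            t += delta + pending
            pending = 0
            anns.append(Annotation(sample=t, symbol=CODE_TO_SYMBOL.get(code, "Q")))
    return anns


def write_annotations(path: str | Path, anns: list[Annotation]) -> None:
    """Serialize annotations (must be time-ordered) to the binary format."""
    out = bytearray()
    prev = 0
    for a in anns:
        if a.symbol not in SYMBOL_TO_CODE:
            raise ValidationError(f"no WFDB code for symbol {a.symbol!r}")
        delta = a.sample - prev
        if delta < 0:
            raise ValidationError("annotations must be time-ordered")
        if delta > 1023:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (SYMBOL_TO_CODE[a.symbol] << 10) | delta)
        if a.aux:
            raw = a.aux.encode("latin-1")
            out += struct.pack("<H", (_AUX << 10) | len(raw))
            out += raw
            if len(raw) & 1:
                out += b"\x00"
        prev = a.sample
    out += struct.pack("<H", 0)  # end of file
    Path(path).write_bytes(bytes(out))


def read_sampling_frequency(header_path: str | Path, default: float = 128.0) -> float:
    """Sampling frequency from a ``.hea`` header; *default* if absent."""
    p = Path(header_path)
    if not p.exists():
        return default
    first = p.read_text().splitlines()[0].split()
    # record_name n_sig [fs [...]]
    if len(first) >= 3:
        return float(first[2].split("/")[0])
    return default


def write_header(header_path: str | Path, record_name: str, fs: float) -> None:
    Path(header_path).write_text(f"{record_name} 0 {fs:g}\n")
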