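"""Minimal reader for the PhysioNet WFDB file family.

Supports what MIT-BIH-style beat-classification work needs: ``.hea`` header
parsing, signal formats 212 (packed 12-bit pairs) and 16 (little-endian
int16), and MIT annotation (``.atr``) decoding. Samples are converted to
physical units via ``(adc - baseline) / gain``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

# MIT annotation-code -> symbol table (codes 1..41 as used in the MIT-BIH
# family; codes absent here are reserved/unused).
CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "x", 33: "[", 34: "e", 35: "]", 36: "n", 37: "@", 38: "f",
    39: "(", 40: ")", 41: "r",
}
SYMBOL_TO_CODE = {v: k for k, v in CODE_TO_SYMBOL.items()}

#: Symbols that denote a beat event (as opposed to rhythm/quality markers).
BEAT_SYMBOLS = frozenset("NLRBAaJSVrFejnE/fQ?")


@dataclass
class SignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    description: str


@dataclass
class Header:
    record_name: str
    n_signals: int
    fs: float
    n_samples: int
    signals: list[SignalSpec]


def read_header(path: Path) -> Header:
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise IOError(f"empty WFDB header: {path}")
    head = lines[0].split()
    record_name = head[0].split("/")[0]
    n_signals = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_signals]:
        parts = ln.split()
        fmt = int(parts[1].split("x")[0].split(":")[0].split("+")[0])
        gain_field = parts[2] if len(parts) > 2 else "200"
        gain_str, _, rest = gain_field.partition("(")
        baseline = None
        if rest:
            baseline = int(rest.split(")")[0])
        gain = float(gain_str.split("/")[0]) or 200.0
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        description = " ".join(parts[8:]) if len(parts) > 8 else f"ch{len(signals)}"
        signals.append(SignalSpec(parts[0], fmt, gain, baseline, description))
    if len(signals) != n_signals:
        raise IOError(f"header {path} declares {n_signals} signals, found {len(signals)}")
    return Header(record_name, n_signals, fs, n_samples, signals)


def _unpack_212(raw: bytes, n_values: int) -> np.ndarray:
    """Unpack format-212 bytes: two 12-bit two's-complement samples per 3 bytes."""
    b = np.frombuffer(raw, dtype=np.uint8)
    n_triplets = len(b) // 3
    b = b[: n_triplets * 3].reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(n_triplets * 2, dtype=np.int32)
    out[0::2] = first
    out[1::2] = second
    out[out > 2047] -= 4096
    return out[:n_values]


def read_signals(dat_path: Path, header: Header) -> np.ndarray:
    """Read all channels, returning an (n_samples, n_signals) float array in physical units."""
    raw = dat_path.read_bytes()
    fmt = header.signals[0].fmt
    if any(s.fmt != fmt for s in header.signals):
        raise IOError(f"{dat_path}: mixed signal formats are not supported")
    n_sig = header.n_signals
    if fmt == 212:
        total = header.n_samples * n_sig if header.n_samples else (len(raw) // 3) * 2
        adc = _unpack_212(raw, total)
    elif fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2").astype(np.int32)
        if header.n_samples:
            adc = adc[: header.n_samples * n_sig]
    else:
        raise IOError(f"{dat_path}: unsupported signal format {fmt}")
    adc = adc[: (len(adc) // n_sig) * n_sig].reshape(-1, n_sig)
    out = np.empty(adc.shape, dtype=float)
    for c, spec in enumerate(header.signals):
        out[:, c] = (adc[:, c] - spec.baseline) / spec.gain
    return out


def read_annotations(path: Path) -> list[tuple[int, str]]:
    """Decode an MIT-format annotation file into (sample_index, symbol) pairs."""
    raw = path.read_bytes()
    words = np.frombuffer(raw[: (len(raw) // 2) * 2], dtype="<u2")
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    pending_skip = 0
    while i < len(words):
        word = int(words[i])
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:  # end of file
            break
        if code == 59:  # SKIP: next two words hold a 32-bit interval, high word first
            if i + 2 >= len(words):
                raise IOError(f"{path}: truncated SKIP pseudo-annotation")
            pending_skip = (int(words[i + 1]) << 16) | int(words[i + 2])
            if pending_skip >= 1 << 31:
                pending_skip -= 1 << 32
            i += 3
            continue
        if code == 63:  # AUX: interval = byte count, data padded to even length
            i += 1 + (interval + 1) // 2
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN modifiers
            i += 1
            continue
        t += interval + pending_skip
        pending_skip = 0
        symbol = CODE_TO_SYMBOL.get(code)
        if symbol is None:
            raise IOError(f"{path}: unknown annotation code {code}")
        out.append((t, symbol))
        i += 1
    return out
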