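"""Test-only writer for tiny WFDB record fixtures (generated at test time).

Produces a header, a format-212 signal file, and an MIT-format annotation
file so the reader can be exercised without any database download.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ecgcascade._wfdb import SYMBOL_TO_CODE

GAIN = 200.0


def write_wfdb_record(
    directory: Path,
    record_name: str,
    signals: np.ndarray,
    fs: float,
    annotations: list[tuple[int, str]],
    lead_names: list[str] | None = None,
) -> Path:
    """Write ``<record_name>.hea/.dat/.atr``; ``signals`` is (n_samples, n_channels)."""
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[0] < signals.shape[1]:
        signals = signals.T
    n, n_sig = signals.shape
    lead_names = lead_names or [f"ch{i}" for i in range(n_sig)]

    adc = np.clip(np.round(signals * GAIN), -2048, 2047).astype(np.int32)

    header_lines = [f"{record_name} {n_sig} {fs:g} {n}"]
    for c in range(n_sig):
        header_lines.append(
            f"{record_name}.dat 212 {GAIN:g} 11 0 {adc[0, c]} 0 0 {lead_names[c]}"
        )
    (directory / f"{record_name}.hea").write_text("\n".join(header_lines) + "\n")

    flat = adc.reshape(-1)  # sample-major interleave
    if len(flat) % 2:
        flat = np.append(flat, 0)
    out = bytearray()
    for a, b in flat.reshape(-1, 2):
        a12, b12 = int(a) & 0xFFF, int(b) & 0xFFF
        out.append(a12 & 0xFF)
        out.append(((a12 >> 8) & 0x0F) | (((b12 >> 8) & 0x0F) << 4))
        out.append(b12 & 0xFF)
    (directory / f"{record_name}.dat").write_bytes(bytes(out))

    atr = bytearray()
    prev = 0
    for sample_index, symbol in annotations:
        interval = sample_index - prev
        code = SYMBOL_TO_CODE[symbol]
        if interval >= 1024:
            atr += int((59 << 10)).to_bytes(2, "little")
            atr += ((interval >> 16) & 0xFFFF).to_bytes(2, "little")
            atr += (interval & 0xFFFF).to_bytes(2, "little")
            interval = 0
        atr += ((code << 10) | interval).to_bytes(2, "little")
        prev = sample_index
    atr += (0).to_bytes(2, "little")
    (directory / f"{record_name}.atr").write_bytes(bytes(atr))
    return directory / record_name
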