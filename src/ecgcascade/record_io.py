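"""Read and write ECG records, beat annotations, and segmented beat datasets.

Three on-disk dialects are handled:

* WFDB header/signal/annotation triplets (read only), e.g. MIT-BIH records;
* single-column CSV amplitude files, as produced by 128 Hz wearable patches;
* the beat-dataset format: a CSV table of windows plus a JSON metadata
  sidecar (inspectable, diff-able, loss-free round trip).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import _wfdb
from .types import WINDOW_SAMPLES, BeatAnnotation, BeatDataset, ECGRecord

logger = logging.getLogger(__name__)

_DATASET_SCHEMA_VERSION = 1


def read_wfdb_record(
    path: str | Path, channel: int | str | None = 0
) -> tuple[ECGRecord, list[BeatAnnotation]]:
    """Read a WFDB record (``.hea`` + ``.dat`` + ``.atr``) as one channel plus beat annotations.

    Parameters
    ----------
    path
        Record path without extension (``dir/100`` reads ``dir/100.hea`` etc.).
    channel
        Channel index or lead name. Defaults to channel 0 (conventionally
        MLII in MIT-BIH). ``None`` on a multi-channel record raises, listing
        the available leads.

    Non-beat annotations (rhythm changes, signal-quality markers) are dropped;
    retained annotations keep their original sample indices.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise IOError(f"missing WFDB header file: {hea}")
    header = _wfdb.read_header(hea)
    dat = path.parent / header.signals[0].file_name
    if not dat.exists():
        raise IOError(f"missing WFDB signal file: {dat}")
    signals = _wfdb.read_signals(dat, header)

    leads = [s.description for s in header.signals]
    if channel is None:
        if header.n_signals > 1:
            raise ValueError(
                f"record {header.record_name} has {header.n_signals} channels "
                f"({', '.join(leads)}); select one by index or name"
            )
        idx = 0
    elif isinstance(channel, str):
        if channel not in leads:
            raise ValueError(f"no lead named {channel!r}; available: {', '.join(leads)}")
        idx = leads.index(channel)
    else:
        if not 0 <= channel < header.n_signals:
            raise ValueError(f"channel {channel} out of range; available: {', '.join(leads)}")
        idx = channel

    record = ECGRecord(
        record_id=header.record_name,
        sampling_rate_hz=header.fs,
        samples=signals[:, idx],
        lead_name=leads[idx],
    )

    atr = path.with_suffix(".atr")
    if not atr.exists():
        raise IOError(f"missing WFDB annotation file: {atr}")
    raw_anns = _wfdb.read_annotations(atr)
    annotations = []
    n_dropped = 0
    for sample_index, symbol in raw_anns:
        if symbol in _wfdb.BEAT_SYMBOLS and sample_index < len(record):
            annotations.append(BeatAnnotation(sample_index=sample_index, symbol=symbol))
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("record %s: dropped %d non-beat annotations", record.record_id, n_dropped)
    return record, annotations


def read_csv_record(path: str | Path, sampling_rate_hz: float) -> ECGRecord:
    """Read a single-column CSV of amplitudes (optional one-line header)."""
    path = Path(path)
    if sampling_rate_hz <= 0:
        raise ValueError(f"sampling_rate_hz must be positive, got {sampling_rate_hz}")
    lines = path.read_text().splitlines()
    values: list[float] = []
    for lineno, line in enumerate(lines, start=1):
        text = line.strip()
        if not text:
            continue
        try:
            values.append(float(text))
        except ValueError:
            if lineno == 1:  # a single header line is allowed
                continue
            raise ValueError(f"{path}:{lineno}: non-numeric amplitude {text!r}") from None
    if not values:
        raise ValueError(f"{path}: no samples found")
    return ECGRecord(
        record_id=path.stem, sampling_rate_hz=float(sampling_rate_hz), samples=np.array(values)
    )


def read_annotation_json(path: str | Path) -> list[BeatAnnotation]:
    """Read a JSON annotation sidecar (list of {sample_index, symbol})."""
    entries = json.loads(Path(path).read_text())
    return [BeatAnnotation(int(e["sample_index"]), str(e["symbol"])) for e in entries]


def write_annotation_json(annotations: list[BeatAnnotation], path: str | Path) -> None:
    payload = [{"sample_index": a.sample_index, "symbol": a.symbol} for a in annotations]
    Path(path).write_text(json.dumps(payload, indent=1))


def write_beat_dataset(dataset: BeatDataset, path: str | Path) -> None:
    """Write a beat dataset as ``<path>.csv`` + ``<path>.json`` sidecar."""
    path = Path(path)
    cols = {
        "record_id": dataset.record_ids_per_beat,
        "r_peak_index": dataset.r_peak_indices,
        "original_symbol": dataset.original_symbols,
        "label": dataset.labels,
    }
    window_frame = pd.DataFrame(
        dataset.windows, columns=[f"w{j:03d}" for j in range(WINDOW_SAMPLES)]
    )
    frame = pd.concat([pd.DataFrame(cols), window_frame], axis=1)
    frame.to_csv(path.with_suffix(".csv"), index=False, float_format="%.9g")
    meta = {
        "schema_version": _DATASET_SCHEMA_VERSION,
        "split": dataset.split,
        "label_space": list(dataset.label_space),
        "n_beats": len(dataset),
        "window_samples": WINDOW_SAMPLES,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_beat_dataset(path: str | Path) -> BeatDataset:
    """Read a beat dataset written by :func:`write_beat_dataset`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta.get("schema_version") != _DATASET_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: unsupported beat-dataset schema version {meta.get('schema_version')!r}"
        )
    if meta.get("window_samples") != WINDOW_SAMPLES:
        raise ValueError(
            f"{path}: window length {meta.get('window_samples')} != {WINDOW_SAMPLES}"
        )
    frame = pd.read_csv(path.with_suffix(".csv"), dtype={"record_id": str})
    window_cols = [c for c in frame.columns if c.startswith("w")]
    if len(window_cols) != WINDOW_SAMPLES:
        raise ValueError(f"{path}: found {len(window_cols)} window columns, need {WINDOW_SAMPLES}")
    if len(frame) != meta["n_beats"]:
        raise ValueError(f"{path}: row count {len(frame)} != declared {meta['n_beats']}")
    if len(frame):
        windows = frame[window_cols].to_numpy(dtype=float)
        labels = frame["label"].to_numpy(dtype=object)
        record_ids = frame["record_id"].to_numpy(dtype=object)
        r_peaks = frame["r_peak_index"].to_numpy(dtype=int)
        symbols = frame["original_symbol"].to_numpy(dtype=object)
    else:
        windows = np.empty((0, WINDOW_SAMPLES))
        labels = record_ids = symbols = np.array([], dtype=object)
        r_peaks = np.array([], dtype=int)
    return BeatDataset(
        windows=windows,
        labels=labels,
        record_ids_per_beat=record_ids,
        r_peak_indices=r_peaks,
        original_symbols=symbols,
        split=meta["split"],
        label_space=tuple(meta["label_space"]),
    )
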