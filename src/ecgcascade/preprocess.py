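"""Signal conditioning and heartbeat segmentation.

The pipeline order is fixed: Fourier resampling to the 360 Hz working rate,
two-median-filter baseline-wander removal, per-record min-max amplitude
normalization to [0, 1], then 600 ms (216-sample) windowing centred on each
annotated R-peak. A Pan-Tompkins-style detector covers unannotated signals.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np
from scipy import ndimage, signal

from .types import (
    HALF_WINDOW,
    WINDOW_SAMPLES,
    WORKING_RATE_HZ,
    BeatAnnotation,
    ECGRecord,
    Heartbeat,
)

logger = logging.getLogger(__name__)

#: Median-filter widths for baseline estimation, seconds.
BASELINE_FILTER_WIDTHS_S = (0.2, 0.6)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def resample_signal(record: ECGRecord, target_rate_hz: float) -> ECGRecord:
    """Resample via the Fourier (sinc) method; length scales by target/source rate."""
    if target_rate_hz <= 0:
        raise ValueError(f"target_rate_hz must be positive, got {target_rate_hz}")
    if target_rate_hz == record.sampling_rate_hz:
        return record
    n_out = _round_half_away(len(record) * target_rate_hz / record.sampling_rate_hz)
    resampled = signal.resample(record.samples, n_out)
    return ECGRecord(
        record_id=record.record_id,
        sampling_rate_hz=float(target_rate_hz),
        samples=resampled,
        lead_name=record.lead_name,
    )


def _kernel_samples(width_s: float, rate_hz: float) -> int:
    k = _round_half_away(width_s * rate_hz)
    return k + 1 if k % 2 == 0 else k


def remove_baseline(record: ECGRecord) -> ECGRecord:
    """Subtract the baseline-wander estimate from the signal.

    The baseline is the 600 ms median filter applied to the output of the
    200 ms median filter on the raw signal (the classic cascade); widths are
    converted to odd sample counts at the record's rate, and edges use
    reflect padding.
    """
    rate = record.sampling_rate_hz
    k_short = _kernel_samples(BASELINE_FILTER_WIDTHS_S[0], rate)
    k_long = _kernel_samples(BASELINE_FILTER_WIDTHS_S[1], rate)
    if len(record) < k_long:
        raise ValueError(
            f"record {record.record_id!r} has {len(record)} samples, shorter than "
            f"the {k_long}-sample baseline filter"
        )
    stage1 = ndimage.median_filter(record.samples, size=k_short, mode="reflect")
    baseline = ndimage.median_filter(stage1, size=k_long, mode="reflect")
    return ECGRecord(
        record_id=record.record_id,
        sampling_rate_hz=rate,
        samples=record.samples - baseline,
        lead_name=record.lead_name,
    )


def normalize_amplitude(record: ECGRecord) -> ECGRecord:
    """Per-record min-max rescaling onto [0, 1]; a constant record maps to zeros."""
    lo = record.samples.min()
    hi = record.samples.max()
    if hi > lo:
        scaled = (record.samples - lo) / (hi - lo)
    else:
        scaled = np.zeros_like(record.samples)
    return ECGRecord(
        record_id=record.record_id,
        sampling_rate_hz=record.sampling_rate_hz,
        samples=scaled,
        lead_name=record.lead_name,
    )


def rescale_annotations(
    annotations: list[BeatAnnotation], source_rate_hz: float, target_rate_hz: float
) -> list[BeatAnnotation]:
    """Map annotation indices through a rate change: round(index * target/source)."""
    if source_rate_hz <= 0 or target_rate_hz <= 0:
        raise ValueError("sampling rates must be positive")
    ratio = target_rate_hz / source_rate_hz
    return [
        BeatAnnotation(sample_index=_round_half_away(a.sample_index * ratio), symbol=a.symbol)
        for a in annotations
    ]


def segment_heartbeats(
    record: ECGRecord,
    annotations: list[BeatAnnotation],
    label_map: Mapping[str, str],
) -> list[Heartbeat]:
    """Cut one 216-sample window per annotated beat at the 360 Hz working rate.

    Windows span ``[index - 108, index + 108)``. Beats within 108 samples of
    either record edge, and beats whose symbol is absent from ``label_map``,
    are dropped with a logged count.
    """
    if not np.isclose(record.sampling_rate_hz, WORKING_RATE_HZ):
        raise ValueError(
            f"segmentation requires the {WORKING_RATE_HZ:g} Hz working rate, "
            f"record {record.record_id!r} is at {record.sampling_rate_hz:g} Hz"
        )
    n = len(record)
    beats: list[Heartbeat] = []
    n_edge = 0
    n_unmapped = 0
    for ann in annotations:
        if not HALF_WINDOW <= ann.sample_index <= n - HALF_WINDOW:
            n_edge += 1
            continue
        label = label_map.get(ann.symbol)
        if label is None:
            n_unmapped += 1
            continue
        window = record.samples[ann.sample_index - HALF_WINDOW : ann.sample_index + HALF_WINDOW]
        beats.append(
            Heartbeat(
                record_id=record.record_id,
                window=window,
                r_peak_index=ann.sample_index,
                label=label,
                original_symbol=ann.symbol,
            )
        )
    if n_edge:
        logger.info("record %s: dropped %d beats within %d samples of an edge",
                    record.record_id, n_edge, HALF_WINDOW)
    if n_unmapped:
        logger.info("record %s: dropped %d beats with unmapped symbols",
                    record.record_id, n_unmapped)
    assert all(b.window.shape == (WINDOW_SAMPLES,) for b in beats)
    return beats


def detect_r_peaks(record: ECGRecord) -> list[int]:
    """Locate R-peaks in a preprocessed signal (Pan-Tompkins-style).

    Differentiate, square, integrate over a 150 ms moving window, threshold
    adaptively, and enforce a 200 ms refractory period (the smaller of two
    competing detections is discarded). Each detection is snapped to the
    local signal maximum within +-50 ms. Returns strictly increasing indices;
    an empty list for flat signals.
    """
    x = record.samples
    rate = record.sampling_rate_hz
    if x.max() - x.min() <= 1e-12:
        return []
    diff = np.diff(x, prepend=x[0])
    energy = diff * diff
    win = max(1, int(round(0.150 * rate)))
    feature = np.convolve(energy, np.ones(win) / win, mode="same")
    # wide (ventricular-style) QRS complexes carry far less derivative energy
    # than narrow spikes, so the level term is kept low and the noise floor
    # (median) supplies the second bound
    threshold = max(0.03 * feature.max(), 2.5 * float(np.median(feature)))
    refractory = int(round(0.200 * rate))
    candidates, _ = signal.find_peaks(feature, height=threshold, distance=refractory)

    snap = int(round(0.050 * rate))
    peaks: list[int] = []
    for c in candidates:
        lo = max(0, c - snap)
        hi = min(len(x), c + snap + 1)
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    # snapping can merge neighbours; keep the larger of any pair closer than
    # the refractory period
    peaks = sorted(set(peaks))
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < refractory:
            if x[p] > x[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    return kept
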