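"""Core domain containers shared across the pipeline.

All sample indices are 0-based into the signal they annotate; all rates are
in Hz. The working rate of the classification pipeline is 360 Hz, at which a
600 ms beat window is exactly 216 samples (108 before and 108 after the
R-peak).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

#: Samples per heartbeat window at the 360 Hz working rate (600 ms).
WINDOW_SAMPLES = 216
#: Samples before (and after) the R-peak inside a window.
HALF_WINDOW = 108
#: The fixed working sampling rate of the classifier, Hz.
WORKING_RATE_HZ = 360.0

#: Canonical label order used for tie-breaking and reporting. "A" (abnormal,
#: the binary stage's positive class) always sorts last.
LABEL_ORDER = ("N", "S", "V", "F", "Q", "A")

FIVE_CLASS = ("N", "S", "V", "F", "Q")
TWO_CLASS = ("N", "A")
FOUR_CLASS = ("S", "V", "F", "Q")


@dataclass
class ECGRecord:
    """One continuous single-lead ECG signal."""

    record_id: str
    sampling_rate_hz: float
    samples: np.ndarray
    lead_name: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError(f"sampling_rate_hz must be positive, got {self.sampling_rate_hz}")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"record {self.record_id!r} contains non-finite samples")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate_hz


@dataclass(frozen=True)
class BeatAnnotation:
    """An annotated beat: R-peak sample index plus its original symbol."""

    sample_index: int
    symbol: str

    def __post_init__(self) -> None:
        if self.sample_index < 0:
            raise ValueError(f"sample_index must be non-negative, got {self.sample_index}")
        if len(self.symbol) != 1:
            raise ValueError(f"symbol must be a single character, got {self.symbol!r}")


@dataclass(frozen=True)
class Heartbeat:
    """A normalized 216-sample window centred on an R-peak."""

    record_id: str
    window: np.ndarray
    r_peak_index: int
    label: str
    original_symbol: str

    def __post_init__(self) -> None:
        w = np.asarray(self.window, dtype=float)
        object.__setattr__(self, "window", w)
        if w.shape != (WINDOW_SAMPLES,):
            raise ValueError(f"window must have exactly {WINDOW_SAMPLES} samples, got {w.shape}")
        if w.min() < -1e-9 or w.max() > 1 + 1e-9:
            raise ValueError("window values must lie in [0, 1]")


@dataclass
class BeatDataset:
    """A labelled collection of heartbeats with record provenance.

    Stored columnar (an ``(n, 216)`` window matrix plus parallel label /
    provenance arrays) for direct use as a classifier design matrix;
    iteration yields :class:`Heartbeat` views.
    """

    windows: np.ndarray
    labels: np.ndarray
    record_ids_per_beat: np.ndarray
    r_peak_indices: np.ndarray
    original_symbols: np.ndarray
    split: str
    label_space: tuple[str, ...]

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float).reshape(-1, WINDOW_SAMPLES)
        self.labels = np.asarray(self.labels, dtype=object)
        self.record_ids_per_beat = np.asarray(self.record_ids_per_beat, dtype=object)
        self.r_peak_indices = np.asarray(self.r_peak_indices, dtype=int)
        self.original_symbols = np.asarray(self.original_symbols, dtype=object)
        n = self.windows.shape[0]
        for name in ("labels", "record_ids_per_beat", "r_peak_indices", "original_symbols"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match {n} windows")
        if self.split not in ("train", "test"):
            raise ValueError(f"split must be 'train' or 'test', got {self.split!r}")
        bad = set(self.labels) - set(self.label_space)
        if bad:
            raise ValueError(f"labels {sorted(bad)} outside label space {self.label_space}")

    @classmethod
    def from_heartbeats(
        cls, beats: Sequence[Heartbeat], split: str, label_space: Sequence[str]
    ) -> "BeatDataset":
        if beats:
            windows = np.stack([b.window for b in beats])
        else:
            windows = np.empty((0, WINDOW_SAMPLES))
        return cls(
            windows=windows,
            labels=np.array([b.label for b in beats], dtype=object),
            record_ids_per_beat=np.array([b.record_id for b in beats], dtype=object),
            r_peak_indices=np.array([b.r_peak_index for b in beats], dtype=int),
            original_symbols=np.array([b.original_symbol for b in beats], dtype=object),
            split=split,
            label_space=tuple(label_space),
        )

    @property
    def record_ids(self) -> set[str]:
        return set(self.record_ids_per_beat)

    def __len__(self) -> int:
        return int(self.windows.shape[0])

    def __iter__(self) -> Iterator[Heartbeat]:
        for i in range(len(self)):
            yield Heartbeat(
                record_id=str(self.record_ids_per_beat[i]),
                window=self.windows[i],
                r_peak_index=int(self.r_peak_indices[i]),
                label=str(self.labels[i]),
                original_symbol=str(self.original_symbols[i]),
            )

    def subset(self, mask: np.ndarray) -> "BeatDataset":
        """Row-subset sharing this dataset's split tag and label space."""
        return BeatDataset(
            windows=self.windows[mask],
            labels=self.labels[mask],
            record_ids_per_beat=self.record_ids_per_beat[mask],
            r_peak_indices=self.r_peak_indices[mask],
            original_symbols=self.original_symbols[mask],
            split=self.split,
            label_space=self.label_space,
        )

    def class_counts(self) -> dict[str, int]:
        return {lab: int(np.sum(self.labels == lab)) for lab in self.label_space}
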