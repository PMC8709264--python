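"""Synthetic annotated ECG cohorts for end-to-end pipeline testing.

Each record is a sum of per-beat templates (parameterized Gaussian bumps for
the P/QRS/T components), a slow sinusoidal baseline wander, and white noise.
Class morphology follows clinical intuition: supraventricular ectopics are
premature with an absent P wave, ventricular ectopics have a wide
high-amplitude QRS with an inverted T, fusion beats are the midpoint of the
normal and ventricular templates (deliberately the hardest class), and
unclassifiable beats are band-limited noise bursts. Templates give analytic
ground truth: the planted R-peak index is the QRS apex sample.

Annotation symbols are drawn from each class's full symbol group (e.g. an S
beat may carry any of A/a/J/S/e/j) so downstream label mapping is exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .record_io import write_annotation_json
from .types import FIVE_CLASS, BeatAnnotation, ECGRecord

#: Annotation symbols available per AAMI class.
CLASS_SYMBOLS: dict[str, tuple[str, ...]] = {
    "N": ("N", "L", "R"),
    "S": ("A", "a", "J", "S", "e", "j"),
    "V": ("V", "E"),
    "F": ("F",),
    "Q": ("/", "f", "Q"),
}

# (amplitude, centre offset s, width s) Gaussian bumps per component
_NORMAL_TEMPLATE = (
    (0.18, -0.170, 0.022),   # P
    (-0.10, -0.028, 0.010),  # Q
    (1.00, 0.000, 0.012),    # R
    (-0.16, 0.030, 0.011),   # S
    (0.30, 0.190, 0.040),    # T
)
_SUPRAVENTRICULAR_TEMPLATE = (
    (0.02, -0.170, 0.022),   # nearly absent P
    (-0.10, -0.028, 0.010),
    (1.00, 0.000, 0.010),
    (-0.16, 0.030, 0.011),
    (0.45, 0.150, 0.030),    # earlier, taller T
)
_VENTRICULAR_TEMPLATE = (
    (1.25, 0.000, 0.035),    # wide, tall QRS, no P
    (-0.30, 0.075, 0.025),
    (-0.35, 0.220, 0.045),   # inverted T
)

#: Support of one beat template, seconds either side of the R-peak.
_TEMPLATE_HALF_SPAN_S = 0.32
#: Prematurity factor applied to the RR interval preceding an S beat.
_PREMATURE_FACTOR = 0.65


@dataclass
class SyntheticConfig:
    """Cohort-generation parameters; ``seed`` fixes the entire cohort."""

    n_records: int = 8
    duration_s: float = 60.0
    sampling_rate_hz: float = 360.0
    class_mix: tuple[float, ...] = (0.70, 0.10, 0.10, 0.05, 0.05)
    mean_rr_s: float = 0.8
    baseline_wander_amp: float = 0.2
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.shape != (5,) or (mix < 0).any() or abs(mix.sum() - 1) > 1e-9:
            raise ValueError("class_mix must be 5 non-negative probabilities summing to 1")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.duration_s <= 2 * 2 * _TEMPLATE_HALF_SPAN_S:
            raise ValueError(f"duration_s must exceed {4 * _TEMPLATE_HALF_SPAN_S:.2f} s")
        if self.mean_rr_s <= 0 or self.noise_sd < 0 or self.baseline_wander_amp < 0:
            raise ValueError("mean_rr_s must be positive; amplitudes non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        """Parse a flat ``key = value`` config file."""
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = (p.strip() for p in line.partition("="))
            if key == "class_mix":
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif key in ("n_records", "seed"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


def _gauss_bumps(t: np.ndarray, template) -> np.ndarray:
    out = np.zeros_like(t)
    for amp, mu, sigma in template:
        out += amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    return out


def _beat_waveform(t: np.ndarray, label: str, rng: np.random.Generator) -> np.ndarray:
    """Evaluate one beat's template at offsets ``t`` (seconds from the R-peak)."""
    if label == "N":
        return _gauss_bumps(t, _NORMAL_TEMPLATE)
    if label == "S":
        return _gauss_bumps(t, _SUPRAVENTRICULAR_TEMPLATE)
    if label == "V":
        return _gauss_bumps(t, _VENTRICULAR_TEMPLATE)
    if label == "F":
        return 0.5 * (_gauss_bumps(t, _NORMAL_TEMPLATE) + _gauss_bumps(t, _VENTRICULAR_TEMPLATE))
    if label == "Q":
        # band-limited noise burst under a Gaussian envelope, plus a narrow
        # apex spike so the planted R-peak is the true local maximum
        envelope = np.exp(-0.5 * (t / 0.10) ** 2)
        noise = rng.normal(0, 0.35, size=t.shape)
        kernel = np.ones(5) / 5
        smooth = np.convolve(noise, kernel, mode="same")
        return smooth * envelope + 0.9 * np.exp(-0.5 * (t / 0.008) ** 2)
    raise ValueError(f"unknown class label {label!r}")


def generate_record(
    config: SyntheticConfig, record_index: int
) -> tuple[ECGRecord, list[BeatAnnotation], list[str]]:
    """Generate one annotated record with its ground-truth class labels.

    The per-record random stream is derived from ``(config.seed,
    record_index)``, so cohorts are extensible without perturbing existing
    records.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), int(record_index)]))
    fs = config.sampling_rate_hz
    n = int(round(config.duration_s * fs))
    t_axis = np.arange(n) / fs

    # slow baseline wander: two incommensurate low-frequency sinusoids
    f1, f2 = rng.uniform(0.12, 0.35, size=2)
    p1, p2 = rng.uniform(0, 2 * math.pi, size=2)
    x = config.baseline_wander_amp * (
        np.sin(2 * math.pi * f1 * t_axis + p1) + 0.5 * np.sin(2 * math.pi * f2 * t_axis + p2)
    )
    x += rng.normal(0, config.noise_sd, size=n)

    labels: list[str] = []
    annotations: list[BeatAnnotation] = []
    t = _TEMPLATE_HALF_SPAN_S + abs(rng.normal(0.1, 0.05))
    rr_sd = 0.05 * config.mean_rr_s
    while t < config.duration_s - _TEMPLATE_HALF_SPAN_S:
        label = FIVE_CLASS[rng.choice(5, p=np.asarray(config.class_mix, dtype=float))]
        if label == "S":  # premature: shrink the interval leading into this beat
            t -= (1 - _PREMATURE_FACTOR) * config.mean_rr_s
            if annotations and t * fs - annotations[-1].sample_index < 0.30 * fs:
                t = annotations[-1].sample_index / fs + 0.30
            t = max(t, _TEMPLATE_HALF_SPAN_S)
        r_idx = int(round(t * fs))
        if r_idx >= n - int(_TEMPLATE_HALF_SPAN_S * fs):
            break
        lo = max(0, r_idx - int(round(_TEMPLATE_HALF_SPAN_S * fs)))
        hi = min(n, r_idx + int(round(_TEMPLATE_HALF_SPAN_S * fs)) + 1)
        offsets = (np.arange(lo, hi) - r_idx) / fs
        x[lo:hi] += _beat_waveform(offsets, label, rng)
        symbol = CLASS_SYMBOLS[label][rng.integers(len(CLASS_SYMBOLS[label]))]
        annotations.append(BeatAnnotation(sample_index=r_idx, symbol=symbol))
        labels.append(label)
        t = r_idx / fs + max(0.35, rng.normal(config.mean_rr_s, rr_sd))

    record = ECGRecord(
        record_id=f"SYN{record_index:03d}",
        sampling_rate_hz=fs,
        samples=x,
        lead_name="synthetic",
    )
    return record, annotations, labels


def generate_cohort(
    config: SyntheticConfig,
) -> list[tuple[ECGRecord, list[BeatAnnotation], list[str]]]:
    """Generate ``config.n_records`` records with independent random streams."""
    return [generate_record(config, i) for i in range(config.n_records)]


def write_record(
    record: ECGRecord, annotations: list[BeatAnnotation], out_dir: str | Path
) -> tuple[Path, Path]:
    """Write a record as ``<id>.csv`` (one amplitude per row) + ``<id>.annotations.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{record.record_id}.csv"
    csv_path.write_text(
        "amplitude\n" + "\n".join(f"{v:.9g}" for v in record.samples) + "\n"
    )
    ann_path = out_dir / f"{record.record_id}.annotations.json"
    write_annotation_json(annotations, ann_path)
    return csv_path, ann_path
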