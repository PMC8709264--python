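from __future__ import annotations

import numpy as np
import pytest

from ecgcascade.synthetic_ecg import SyntheticConfig, generate_record
from ecgcascade.types import ECGRecord


@pytest.fixture(scope="session")
def clean_record():
    """One low-noise synthetic record with its annotations and truth labels."""
    config = SyntheticConfig(n_records=1, duration_s=30.0, seed=7)
    return generate_record(config, 0)


@pytest.fixture()
def flat_record():
    return ECGRecord(record_id="flat", sampling_rate_hz=360.0, samples=np.zeros(3600))


def brute_force_baseline(samples: np.ndarray, rate_hz: float) -> np.ndarray:
    """Independent sliding-median baseline-removal reference.

    Symmetric (edge-repeating) padding, 200 ms then 600 ms cascade, output =
    raw - baseline. Deliberately naive: one np.median call per sample.
    """

    def sliding_median(x: np.ndarray, width_s: float) -> np.ndarray:
        k = int(np.floor(width_s * rate_hz + 0.5))
        if k % 2 == 0:
            k += 1
        half = k // 2
        padded = np.pad(x, half, mode="symmetric")
        return np.array([np.median(padded[i : i + k]) for i in range(len(x))])

    baseline = sliding_median(sliding_median(samples, 0.2), 0.6)
    return samples - baseline
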