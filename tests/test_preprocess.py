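from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgcascade import preprocess
from ecgcascade.dataset_builder import LABEL_MAP
from ecgcascade.types import BeatAnnotation, ECGRecord

from conftest import brute_force_baseline


def make_record(samples, rate=360.0, record_id="r"):
    return ECGRecord(record_id=record_id, sampling_rate_hz=rate, samples=np.asarray(samples, float))


class TestResample:
    def test_length_scales_by_rate_ratio(self):
        record = make_record(np.zeros(9000), rate=300)
        out = preprocess.resample_signal(record, 360)
        assert len(out) == 10800
        assert out.sampling_rate_hz == 360

    def test_dc_preserved(self):
        record = make_record(np.full(3000, 0.7), rate=300)
        out = preprocess.resample_signal(record, 360)
        assert np.allclose(out.samples, 0.7, atol=1e-9)

    def test_sinusoid_matches_closed_form(self):
        """Fourier resampling of a band-limited tone equals the analytic signal."""
        rate_in, rate_out, freq = 300.0, 360.0, 5.0
        t_in = np.arange(900) / rate_in  # integer number of cycles
        record = make_record(np.sin(2 * np.pi * freq * t_in), rate=rate_in)
        out = preprocess.resample_signal(record, rate_out)
        t_out = np.arange(len(out)) / rate_out
        expected = np.sin(2 * np.pi * freq * t_out)
        interior = slice(50, -50)
        rms = np.sqrt(np.mean((out.samples[interior] - expected[interior]) ** 2))
        assert rms < 1e-6

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            preprocess.resample_signal(make_record(np.zeros(100)), -1)


class TestRemoveBaseline:
    def test_constant_signal_maps_to_zero(self):
        out = preprocess.remove_baseline(make_record(np.full(1000, 3.3)))
        assert np.allclose(out.samples, 0, atol=1e-12)

    def test_slow_ramp_suppressed(self):
        ramp = np.linspace(0, 2.0, 2000)
        out = preprocess.remove_baseline(make_record(ramp))
        interior = out.samples[300:-300]
        assert np.max(np.abs(interior)) < 0.05 * np.ptp(ramp)

    def test_narrow_spike_preserved(self):
        x = np.zeros(2000)
        spike = np.exp(-0.5 * ((np.arange(2000) - 1000) / 4.0) ** 2)  # ~30 ms wide
        x += spike
        out = preprocess.remove_baseline(make_record(x))
        assert abs(out.samples[1000] - 1.0) < 0.01

    def test_matches_brute_force_reference(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, size=800)
        out = preprocess.remove_baseline(make_record(x))
        assert np.array_equal(out.samples, brute_force_baseline(x, 360.0))

    def test_record_shorter_than_kernel_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            preprocess.remove_baseline(make_record(np.zeros(100)))


class TestNormalize:
    @pytest.mark.parametrize(
        "samples, expected",
        [
            ([-2.0, 0.0, 2.0], [0.0, 0.5, 1.0]),
            ([0.0, 0.25, 1.0], [0.0, 0.25, 1.0]),
            ([4.0, 4.0, 4.0], [0.0, 0.0, 0.0]),
        ],
    )
    def test_minmax_cases(self, samples, expected):
        out = preprocess.normalize_amplitude(make_record(samples))
        assert np.allclose(out.samples, expected)

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2, max_size=50,
        )
    )
    @settings(deadline=None)
    def test_idempotent(self, values):
        record = make_record(values)
        once = preprocess.normalize_amplitude(record)
        twice = preprocess.normalize_amplitude(once)
        assert np.allclose(once.samples, twice.samples, atol=1e-12)
        assert once.samples.min() >= 0 and once.samples.max() <= 1


class TestRescaleAnnotations:
    @pytest.mark.parametrize(
        "index, expected",
        [(300, 360), (0, 0), (133, 160)],  # 133 * 1.2 = 159.6 rounds up
    )
    def test_index_mapping_300_to_360(self, index, expected):
        out = preprocess.rescale_annotations([BeatAnnotation(index, "N")], 300, 360)
        assert out[0].sample_index == expected
        assert out[0].symbol == "N"

    @given(st.lists(st.integers(min_value=0, max_value=10**6), min_size=0, max_size=30))
    @settings(deadline=None)
    def test_order_and_symbols_preserved(self, indices):
        indices = sorted(indices)
        anns = [BeatAnnotation(i, "V") for i in indices]
        out = preprocess.rescale_annotations(anns, 128, 360)
        assert [a.symbol for a in out] == ["V"] * len(indices)
        assert all(b.sample_index >= a.sample_index for a, b in zip(out, out[1:]))


class TestSegmentation:
    def test_window_spans_108_samples_each_side(self):
        record = make_record(np.linspace(0, 1, 216))
        beats = preprocess.segment_heartbeats(record, [BeatAnnotation(108, "N")], LABEL_MAP)
        assert len(beats) == 1
        assert beats[0].window.shape == (216,)
        assert np.array_equal(beats[0].window, record.samples)

    def test_edge_beats_dropped(self):
        record = make_record(np.full(1000, 0.5))
        beats = preprocess.segment_heartbeats(
            record, [BeatAnnotation(50, "N"), BeatAnnotation(950, "N")], LABEL_MAP
        )
        assert beats == []

    def test_interior_count_conserved(self):
        record = make_record(np.full(3600, 0.5))
        anns = [BeatAnnotation(200 + 300 * i, "N") for i in range(7)]
        beats = preprocess.segment_heartbeats(record, anns, LABEL_MAP)
        assert len(beats) == 7
        assert all(b.label == "N" for b in beats)

    def test_wrong_rate_rejected(self):
        record = make_record(np.full(1000, 0.5), rate=300)
        with pytest.raises(ValueError, match="360"):
            preprocess.segment_heartbeats(record, [], LABEL_MAP)

    def test_windows_stay_in_unit_interval(self, clean_record):
        from ecgcascade.workflow import preprocess_record

        record, annotations, _ = clean_record
        beats = preprocess_record(record, annotations)
        for beat in beats:
            assert beat.window.shape == (216,)
            assert beat.window.min() >= 0 and beat.window.max() <= 1


class TestRPeakDetection:
    @staticmethod
    def planted_record(indices, amps=None, n=7200, noise=0.005, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, noise, size=n)
        amps = amps or [1.0] * len(indices)
        grid = np.arange(n)
        for idx, amp in zip(indices, amps):
            x += amp * np.exp(-0.5 * ((grid - idx) / 4.0) ** 2)
        return make_record(x)

    def test_planted_beats_recovered_within_25_ms(self):
        truth = [400 + 650 * i for i in range(10)]
        record = self.planted_record(truth)
        peaks = preprocess.detect_r_peaks(record)
        assert len(peaks) == 10
        assert all(min(abs(p - t) for t in truth) <= 9 for p in peaks)  # 25 ms at 360 Hz

    def test_flat_signal_yields_no_peaks(self, flat_record):
        assert preprocess.detect_r_peaks(flat_record) == []

    def test_refractory_keeps_larger_of_close_pair(self):
        record = self.planted_record([1000, 1036], amps=[0.6, 1.0])  # 100 ms apart
        peaks = preprocess.detect_r_peaks(record)
        assert len(peaks) == 1
        assert abs(peaks[0] - 1036) <= 2

    def test_output_strictly_increasing(self, clean_record):
        record, _, _ = clean_record
        from ecgcascade.preprocess import normalize_amplitude, remove_baseline

        peaks = preprocess.detect_r_peaks(normalize_amplitude(remove_baseline(record)))
        assert all(b > a for a, b in zip(peaks, peaks[1:]))
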