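"""Sensor model, signal synthesis, and dataset assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import find_peaks

from gyrowave.synthetic import (CHANNELS, GyroSpec, RecordingProtocol,
                                adc_code, build_dataset, downsample,
                                generate_rate_signal, get_motion,
                                load_dataset, quantize_adc, rate_to_voltage,
                                save_dataset, voltage_to_rate)


class TestSensorModel:
    def test_affine_map_printed_values(self, default_spec):
        assert rate_to_voltage(0.0, default_spec) == pytest.approx(2.5)
        assert rate_to_voltage(90.0, default_spec) == pytest.approx(4.5)
        assert rate_to_voltage(-90.0, default_spec) == pytest.approx(0.5)

    def test_saturation_beyond_rate_limit(self, default_spec):
        assert rate_to_voltage(150.0, default_spec) == pytest.approx(4.5)
        assert rate_to_voltage(-500.0, default_spec) == pytest.approx(0.5)

    def test_round_trip_exact_within_range(self, default_spec):
        rates = np.linspace(-90, 90, 181)
        back = voltage_to_rate(rate_to_voltage(rates, default_spec),
                               default_spec)
        np.testing.assert_allclose(back, rates, atol=1e-12)

    def test_round_trip_with_quantization_bounded(self, default_spec):
        rates = np.linspace(-90, 90, 2001)
        v = quantize_adc(rate_to_voltage(rates, default_spec), default_spec)
        back = voltage_to_rate(v, default_spec)
        step = 5.0 / 255
        bound = default_spec.rate_max * step / (default_spec.v_max
                                                - default_spec.v_zero)
        assert np.max(np.abs(back - rates)) <= bound / 2 + 1e-12

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GyroSpec(v_zero=0.4)  # below v_min


class TestQuantizer:
    def test_midscale_code_and_reconstruction(self, default_spec):
        # independent oracle: round(2.5 / 5 * 255) = 128, 128 * 5 / 255
        assert adc_code(2.5, default_spec) == 128
        assert quantize_adc(2.5, default_spec) == pytest.approx(128 * 5 / 255)
        assert quantize_adc(2.5, default_spec) == pytest.approx(2.5098, abs=1e-4)

    def test_rails(self, default_spec):
        assert adc_code(0.0, default_spec) == 0
        assert quantize_adc(0.0, default_spec) == 0.0
        assert adc_code(5.0, default_spec) == 255
        assert quantize_adc(5.0, default_spec) == pytest.approx(5.0)

    def test_all_codes_round_trip_exactly(self, default_spec):
        # exhaustive scan of the 256 reconstruction levels
        step = 5.0 / 255
        volts = np.arange(256) * step
        np.testing.assert_array_equal(adc_code(volts, default_spec),
                                      np.arange(256))

    def test_halfway_rounds_up(self, default_spec):
        step = 5.0 / 255
        assert adc_code(0.5 * step, default_spec) == 1

    @given(st.floats(min_value=-1.0, max_value=6.0,
                     allow_nan=False, allow_infinity=False))
    @settings(deadline=None, max_examples=50)
    def test_quantization_error_bounded(self, v):
        spec = GyroSpec()
        step = 5.0 / 255
        clamped = np.clip(v, 0.0, 5.0)
        assert abs(float(quantize_adc(v, spec)) - clamped) <= step / 2 + 1e-12


class TestDownsample:
    def test_keeps_every_factor_th(self):
        np.testing.assert_array_equal(
            downsample(np.arange(1, 41), 20), [1, 21])

    def test_identity_at_factor_one(self):
        x = np.arange(7.0)
        np.testing.assert_array_equal(downsample(x, 1), x)

    def test_raw_segment_maps_to_1600_samples(self):
        assert downsample(np.zeros(32000), 20).shape[-1] == 1600

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            downsample(np.arange(4), 0)


class TestGenerateRateSignal:
    FS = 2668.0 / 20  # working sample rate

    def test_standing_class_is_noise_only(self):
        x = generate_rate_signal(1, 72.0, self.FS, seed=0)
        assert x.shape == (2, round(72 * self.FS))
        assert np.all(np.std(x, axis=1) <= 1.1 * 0.5)  # noise floor sd

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_repetition_count_in_expected_band(self, seed):
        # 10-14 repetitions of the motion in a 72 s interval
        x = generate_rate_signal(4, 72.0, self.FS, seed=seed)
        for ch in range(2):
            env = np.convolve(np.abs(x[ch]), np.ones(int(self.FS)) / self.FS,
                              mode="same")
            peaks, _ = find_peaks(env, distance=int(3 * self.FS),
                                  height=0.3 * env.max())
            assert 10 <= len(peaks) <= 14

    def test_deterministic_given_seed(self):
        a = generate_rate_signal(7, 30.0, self.FS, seed=7)
        b = generate_rate_signal(7, 30.0, self.FS, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_below_knee_dominant_classes(self):
        for motion in (2, 8):
            x = generate_rate_signal(motion, 72.0, self.FS, seed=1)
            assert np.std(x[1]) > 3 * np.std(x[0])

    def test_amplitude_respects_sensor_range(self):
        for motion in range(1, 9):
            x = generate_rate_signal(motion, 72.0, self.FS, seed=5,
                                     snr_db=30.0)
            assert np.max(np.abs(x)) <= 90.0 + 5.0  # headroom for noise

    def test_unknown_motion_id(self):
        with pytest.raises(ValueError, match="1..8"):
            generate_rate_signal(9, 10.0, self.FS)


class TestBuildDataset:
    def test_default_protocol_counts(self, default_dataset):
        ds = default_dataset
        assert ds.n_segments == 768
        assert ds.n_patterns == 384
        counts = ds.counts()
        assert (counts["n_segments"] == 48).all()
        per_motion = counts.groupby("motion_id")["n_segments"].sum()
        assert (per_motion == 96).all()

    def test_pairing_consistent(self, default_dataset):
        # pairing oracle: one pattern per (motion, interval, segment) triple
        meta = default_dataset.meta
        triples = set(map(tuple, meta.to_numpy()))
        assert len(triples) == default_dataset.n_patterns

    def test_segment_length_and_rate_bound(self, default_dataset):
        assert default_dataset.pairs.shape == (384, 2, 1600)
        # the ADC reconstruction may exceed the saturation rail by at most
        # half a quantization step (in rate units)
        spec = default_dataset.spec
        half_step = 0.5 * (5.0 / 255) / spec.volts_per_rate
        assert np.max(np.abs(default_dataset.pairs)) <= 90.0 + half_step

    @given(st.integers(1, 3), st.integers(1, 3), st.integers(1, 3))
    @settings(deadline=None, max_examples=10)
    def test_counts_follow_protocol_products(self, motions, intervals, segs):
        protocol = RecordingProtocol(
            n_motions=motions, intervals_per_motion=intervals,
            segments_per_interval=segs, segment_len=64, interval_s=8.0)
        ds = build_dataset(protocol, seed=0)
        assert ds.n_patterns == motions * intervals * segs
        assert ds.n_segments == 2 * ds.n_patterns

    def test_single_motion_protocol(self):
        protocol = RecordingProtocol(n_motions=1, intervals_per_motion=1,
                                     segments_per_interval=6,
                                     segment_len=128, interval_s=12.0)
        ds = build_dataset(protocol, seed=0)
        assert ds.n_segments == 12

    def test_interval_too_short_raises(self):
        protocol = RecordingProtocol(interval_s=10.0)  # needs 72 s of raw data
        with pytest.raises(ValueError, match="raw samples"):
            build_dataset(protocol, seed=0)

    def test_standing_class_separable_by_variance(self, default_dataset):
        ds = default_dataset
        var = ds.pairs.var(axis=2).max(axis=1)  # larger channel variance
        m1 = var[ds.labels == 1]
        rest = var[ds.labels != 1]
        assert m1.max() < rest.min()

    def test_deterministic_serialization(self, tmp_path):
        protocol = RecordingProtocol(n_motions=2, intervals_per_motion=1,
                                     segments_per_interval=2,
                                     segment_len=128, interval_s=6.0)
        p1 = save_dataset(build_dataset(protocol, seed=11), tmp_path / "a")
        p2 = save_dataset(build_dataset(protocol, seed=11), tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()

    def test_csv_round_trip(self, tmp_path):
        protocol = RecordingProtocol(n_motions=3, intervals_per_motion=2,
                                     segments_per_interval=2,
                                     segment_len=128, interval_s=6.0)
        ds = build_dataset(protocol, seed=4)
        save_dataset(ds, tmp_path)
        back = load_dataset(tmp_path)
        np.testing.assert_allclose(back.pairs, ds.pairs, atol=1e-9)
        np.testing.assert_array_equal(back.labels, ds.labels)
        assert back.protocol == ds.protocol
        assert back.spec == ds.spec
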