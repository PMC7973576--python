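"""Acquisition format round-tripping, ADC conversion and throughput."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invisible_ecg import (
    ChannelRole,
    ChannelSpec,
    FormatError,
    RawRecording,
    ValidationError,
    adc_to_millivolts,
    millivolts_to_adc,
    read_recording,
    stream_rate,
    write_recording,
)

SPEC = ChannelSpec("ECG_REF", ChannelRole.ECG_REF, adc_bits=10, vcc=3.3, gain=11000.0)


def _rec(samples, roles=("ecg_ref", "led"), bits=10, fs=1000.0):
    channels = [
        ChannelSpec(f"ch{i}", ChannelRole(r), adc_bits=bits) for i, r in enumerate(roles)
    ]
    return RawRecording(channels=channels, samples=np.asarray(samples), fs=fs)


class TestFileFormat:
    def test_read_parses_header_and_rows(self, tmp_path):
        p = tmp_path / "rec.txt"
        p.write_text(
            "# BEGIN HEADER\n"
            '# {"fs": 1000, "bits": 10, "channels": '
            '[{"name": "ECG_REF", "role": "ecg_ref"}, {"name": "LED", "role": "led"}], '
            '"device_id": "devA"}\n'
            "# END HEADER\n"
            "1\t2\n3\t4\n5\t6\n"
        )
        rec = read_recording(p)
        assert rec.fs == 1000.0
        assert rec.n_samples == 3
        assert len(rec.channels) == 2
        assert rec.channels[0].role is ChannelRole.ECG_REF
        assert rec.device_id == "devA"

    def test_round_trip_is_bit_exact(self, tmp_path):
        rec = _rec([[1, 1023], [512, 0], [7, 900]])
        back = read_recording(write_recording(rec, tmp_path / "a.txt"))
        assert back == rec

    def test_two_writes_are_byte_identical(self, tmp_path):
        rec = _rec([[1, 2], [3, 4]])
        p1 = write_recording(rec, tmp_path / "a.txt")
        p2 = write_recording(rec, tmp_path / "b.txt")
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_recording_round_trips(self, tmp_path):
        rec = _rec(np.empty((0, 2), dtype=int))
        back = read_recording(write_recording(rec, tmp_path / "a.txt"))
        assert back.n_samples == 0
        assert back == rec

    def test_out_of_range_value_names_row_and_channel(self):
        with pytest.raises(ValidationError, match=r"row 1.*ch0|1024"):
            _rec([[5, 5], [1024, 5]])

    def test_malformed_header_raises_format_error(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("# BEGIN HEADER\n# {not json}\n# END HEADER\n1\t2\n")
        with pytest.raises(FormatError):
            read_recording(p)

    def test_missing_header_raises_format_error(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("1\t2\n3\t4\n")
        with pytest.raises(FormatError):
            read_recording(p)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        bits=st.sampled_from([6, 10]),
        n=st.integers(min_value=0, max_value=200),
        n_ch=st.integers(min_value=1, max_value=4),
        fs=st.sampled_from([100.0, 500.0, 1000.0]),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_round_trip_property(self, tmp_path_factory, bits, n, n_ch, fs, seed):
        rng = np.random.default_rng(seed)
        samples = rng.integers(0, 2**bits, size=(n, n_ch))
        rec = _rec(samples, roles=["ecg_exp"] * n_ch, bits=bits, fs=fs)
        p = tmp_path_factory.mktemp("rt") / "r.txt"
        assert read_recording(write_recording(rec, p)) == rec


class TestAdcConversion:
    def test_midscale_maps_to_zero(self):
        assert adc_to_millivolts(512, SPEC) == pytest.approx(0.0)

    def test_count_zero_value(self):
        # (0/1024 - 0.5) * 3.3 / 11000 * 1000
        assert adc_to_millivolts(0, SPEC) == pytest.approx(-0.15)

    def test_full_span(self):
        span = adc_to_millivolts(1023, SPEC) - adc_to_millivolts(0, SPEC)
        assert span == pytest.approx(1023 / 1024 * 3.3 / 11000 * 1000)

    def test_strictly_monotone_and_midpoint_within_one_lsb(self):
        counts = np.arange(0, 1024)
        mv = adc_to_millivolts(counts, SPEC)
        assert np.all(np.diff(mv) > 0)
        lsb_mv = 3.3 / 11000 * 1000 / 1024
        assert abs(mv[512]) <= lsb_mv

    def test_out_of_range_counts_rejected(self):
        with pytest.raises(ValidationError):
            adc_to_millivolts([0, 1024], SPEC)

    def test_quantization_inverse_round_trips_in_range(self, rng):
        mv = rng.uniform(-0.14, 0.14, 100)
        counts = millivolts_to_adc(mv, SPEC)
        back = adc_to_millivolts(counts, SPEC)
        lsb_mv = 3.3 / 11000 * 1000 / 1024
        assert np.all(np.abs(back - mv) <= lsb_mv)

    def test_saturating_inputs_clip_at_rails(self):
        counts = millivolts_to_adc([-10.0, 10.0], SPEC)
        assert list(counts) == [0, 1023]


class TestStreamRate:
    def test_study_configuration(self):
        assert stream_rate(1000, 7) == 56.0

    def test_unit_case(self):
        assert stream_rate(1, 1) == pytest.approx(0.008)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        fs=st.floats(min_value=1, max_value=10000),
        fb=st.integers(min_value=1, max_value=64),
        a=st.integers(min_value=1, max_value=5),
    )
    def test_linearity(self, fs, fb, a):
        assert stream_rate(a * fs, fb) == pytest.approx(a * stream_rate(fs, fb))
        assert stream_rate(fs, a * fb) == pytest.approx(a * stream_rate(fs, fb))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            stream_rate(0, 7)
        with pytest.raises(ValidationError):
            stream_rate(1000, 0)
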