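import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slnet.recordings import (
    BAND_BY_NAME,
    MONTAGE,
    STUDY_BANDS,
    BandDefinition,
    Event,
    MultichannelRecording,
    bandpass_filter,
    channel_montage,
    read_recording,
    segment_epochs,
    write_delimited,
)


def sine_recording(freq, fs=250.0, seconds=8.0, n_channels=1):
    t = np.arange(int(fs * seconds)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))
    return MultichannelRecording(data, fs)


class TestContainers:
    def test_labels_default_to_channel_numbers(self):
        rec = MultichannelRecording(np.zeros((3, 10)), 250.0)
        assert rec.channel_labels == ("Ch01", "Ch02", "Ch03")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            MultichannelRecording(np.zeros((2, 10)), 250.0, ("A", "A"))

    def test_band_edges_validated(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 10.0, 4.0)

    def test_five_study_bands(self):
        names = [b.name for b in STUDY_BANDS]
        assert names == ["delta", "theta", "alpha", "beta", "gamma"]
        assert BAND_BY_NAME["delta"].low == pytest.approx(0.01)
        assert BAND_BY_NAME["gamma"].high == 50.0


class TestMontage:
    @pytest.mark.parametrize(
        "index,electrode,area",
        [(8, "T3", 42), (12, "T4", 21), (6, "F4", 8), (7, "F8", 45), (3, "F7", 47)],
    )
    def test_stated_single_area_channels(self, index, electrode, area):
        entry = channel_montage(index)
        assert entry.electrode == electrode
        assert entry.brodmann == (area,)
        assert not entry.ambiguous

    def test_electrode_order_is_10_20(self):
        names = [m.electrode for m in MONTAGE]
        assert names == ["Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3",
                         "C3", "Cz", "C4", "T4", "T5", "P3", "Pz", "P4",
                         "T6", "O1", "O2"]

    def test_grouped_assignments_flagged_ambiguous(self):
        for idx in (9, 10, 11):
            entry = channel_montage(idx)
            assert entry.ambiguous and set(entry.brodmann) == {1, 2, 5}
        for idx in (13, 17, 18, 19):
            entry = channel_montage(idx)
            assert entry.ambiguous and set(entry.brodmann) == {18, 37}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            channel_montage(0)
        with pytest.raises(ValueError):
            channel_montage(20)


class TestFiltering:
    def test_in_band_sine_preserved(self):
        rec = sine_recording(10.0)
        out = bandpass_filter(rec, BAND_BY_NAME["alpha"])
        rms_in = np.sqrt(np.mean(rec.data[:, 500:-500] ** 2))
        rms_out = np.sqrt(np.mean(out.data[:, 500:-500] ** 2))
        assert rms_out == pytest.approx(rms_in, rel=0.05)

    def test_out_of_band_sine_attenuated_20db(self):
        rec = sine_recording(10.0)
        out = bandpass_filter(rec, BAND_BY_NAME["beta"])
        rms_in = np.sqrt(np.mean(rec.data[:, 500:-500] ** 2))
        rms_out = np.sqrt(np.mean(out.data[:, 500:-500] ** 2))
        assert 20 * np.log10(rms_in / rms_out) >= 20

    def test_zero_signal_stays_zero(self):
        rec = MultichannelRecording(np.zeros((2, 1000)), 250.0)
        out = bandpass_filter(rec, BAND_BY_NAME["theta"])
        assert np.allclose(out.data, 0.0)

    def test_delta_band_low_edge_handled(self):
        # 0.01 Hz low edge at 250 Hz: the low-pass-only fallback must keep
        # slow content and remove fast content
        rec = sine_recording(2.0)
        out = bandpass_filter(rec, BAND_BY_NAME["delta"])
        assert np.sqrt(np.mean(out.data**2)) == pytest.approx(
            np.sqrt(np.mean(rec.data**2)), rel=0.05
        )
        fast = sine_recording(40.0)
        out_fast = bandpass_filter(fast, BAND_BY_NAME["delta"])
        assert np.sqrt(np.mean(out_fast.data**2)) < 0.05

    def test_band_above_nyquist_rejected(self):
        rec = sine_recording(10.0, fs=80.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(rec, BAND_BY_NAME["gamma"])

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    def test_filter_linearity(self, scale):
        rng = np.random.default_rng(3)
        rec = MultichannelRecording(rng.standard_normal((2, 2000)), 250.0)
        scaled = MultichannelRecording(scale * rec.data, 250.0)
        band = BAND_BY_NAME["alpha"]
        out = bandpass_filter(rec, band)
        out_scaled = bandpass_filter(scaled, band)
        np.testing.assert_allclose(out_scaled.data, scale * out.data,
                                   rtol=1e-9, atol=1e-12)


class TestEpoching:
    def test_single_event_covers_recording(self, rng):
        rec = MultichannelRecording(rng.standard_normal((3, 500)), 250.0)
        eps = segment_epochs(rec, [Event("S01", "ES", 0, 0.0, 2.0)])
        assert len(eps) == 1
        np.testing.assert_array_equal(eps.epochs[0].recording.data, rec.data)

    def test_twenty_two_second_epochs(self, rng):
        rec = MultichannelRecording(rng.standard_normal((2, 10000)), 250.0)
        events = [Event("S01", "ES", k, 2.0 * k, 2.0 * (k + 1)) for k in range(20)]
        eps = segment_epochs(rec, events)
        assert len(eps) == 20
        assert all(ep.recording.n_samples == 500 for ep in eps)

    def test_half_open_convention_tiles_recording(self, rng):
        rec = MultichannelRecording(rng.standard_normal((2, 750)), 250.0)
        events = [Event("S", "ES", k, k, k + 1) for k in range(3)]
        eps = segment_epochs(rec, events)
        rebuilt = np.concatenate([ep.recording.data for ep in eps], axis=1)
        np.testing.assert_array_equal(rebuilt, rec.data)

    def test_event_past_end_rejected(self, rng):
        rec = MultichannelRecording(rng.standard_normal((2, 100)), 250.0)
        with pytest.raises(ValueError, match="outside"):
            segment_epochs(rec, [Event("S", "ES", 0, 0.0, 1.0)])

    def test_empty_events_rejected(self, rng):
        rec = MultichannelRecording(rng.standard_normal((2, 100)), 250.0)
        with pytest.raises(ValueError):
            segment_epochs(rec, [])


class TestDelimitedIO:
    def test_round_trip(self, rng, tmp_path):
        labels = tuple(f"Ch{i + 1:02d}" for i in range(19))
        rec = MultichannelRecording(rng.standard_normal((19, 400)), 250.0, labels)
        events = [Event("S01", "ES", 0, 0.0, 1.0)]
        data_path = tmp_path / "rec.tsv"
        side_path = tmp_path / "rec.events.json"
        write_delimited(rec, data_path, events, side_path)
        back, back_events = read_recording(data_path, "delimited", side_path)
        assert back.channel_labels == labels
        assert back.fs == 250.0
        np.testing.assert_allclose(back.data, rec.data, rtol=1e-6)
        assert back_events == events

    def test_event_past_recording_rejected(self, rng, tmp_path):
        rec = MultichannelRecording(rng.standard_normal((2, 100)), 250.0)
        data_path = tmp_path / "rec.tsv"
        side_path = tmp_path / "rec.events.json"
        write_delimited(rec, data_path, [Event("S", "ES", 0, 0.0, 9.0)], side_path)
        with pytest.raises(ValueError, match="past"):
            read_recording(data_path, "delimited", side_path)

    def test_missing_fs_rejected(self, rng, tmp_path):
        rec = MultichannelRecording(rng.standard_normal((2, 50)), 250.0)
        data_path = tmp_path / "rec.tsv"
        write_delimited(rec, data_path)
        with pytest.raises(ValueError, match="sampling rate"):
            read_recording(data_path, "delimited")

    def test_sidecar_fs_used(self, rng, tmp_path):
        rec = MultichannelRecording(rng.standard_normal((2, 50)), 125.0)
        data_path = tmp_path / "rec.tsv"
        side_path = tmp_path / "rec.json"
        write_delimited(rec, data_path, [], side_path)
        with open(side_path) as fh:
            assert json.load(fh)["fs"] == 125.0
        back, _ = read_recording(data_path, "delimited", side_path)
        assert back.fs == 125.0
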