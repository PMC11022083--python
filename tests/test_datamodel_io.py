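"""Data model invariants and the three-file format round trip."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from limbkin import (
    Block,
    ConfigError,
    Event,
    HardwareConfig,
    ProtocolConfig,
    Recording,
    RecordingMeta,
    ValidationError,
    export_csv,
    read_recording,
    validate_recording,
    write_recording,
)
from limbkin.io import ParseError

from conftest import make_recording


class TestConfigInvariants:
    @pytest.mark.parametrize("kwargs", [
        {"range_g": 3},
        {"sampling_rate_hz": 2.0},
        {"sampling_rate_hz": 5000.0},
        {"trigger_edge": "both"},
    ])
    def test_hardware_config_rejects_out_of_range(self, kwargs):
        with pytest.raises(ConfigError):
            HardwareConfig(**kwargs)

    def test_protocol_rejects_overlapping_events(self):
        # 1 s events at one beep per second leave no gap -> allowed;
        # 2 s events at the same rate overlap -> rejected
        ProtocolConfig(stim_rate_mHz=1000, event_samples=1000, sampling_rate_hz=1000)
        with pytest.raises(ConfigError):
            ProtocolConfig(stim_rate_mHz=1000, event_samples=2000, sampling_rate_hz=1000)

    @pytest.mark.parametrize("kwargs", [
        {"mode": "acoustic", "stim_rate_mHz": 0},
        {"event_samples": 0},
        {"repetitions": 0},
        {"mode": "handsfree"},
    ])
    def test_protocol_config_rejects_invalid(self, kwargs):
        with pytest.raises(ConfigError):
            ProtocolConfig(**kwargs)


class TestValidateRecording:
    def test_valid_recording_yields_empty_report(self, random_recording):
        assert validate_recording(random_recording) == []

    def test_short_event_under_protocol_named_in_report(self, rng):
        rec = make_recording(rng, n_blocks=1)
        rec.meta.protocol = ProtocolConfig(
            mode="external_trigger",
            event_samples=rec.blocks[0].events[0].n_samples + 1,
        )
        report = validate_recording(rec)
        assert any("event (block 0, event 0)" in p and "samples" in p for p in report)

    def test_decreasing_block_id_flagged(self, rng):
        rec = make_recording(rng, n_blocks=2)
        rec.blocks[1].block_id = 0
        for e in rec.blocks[1].events:
            e.block_id = 0
        assert any("contiguity" in p for p in validate_recording(rec))

    def test_sample_id_gap_flagged(self, rng):
        rec = make_recording(rng, n_blocks=1)
        rec.blocks[0].events[0].sample_ids += 5
        assert any("sample_ids not contiguous" in p for p in validate_recording(rec))

    def test_meta_count_mismatch_flagged(self, tiny_recording):
        tiny_recording.meta.n_events = 7
        assert any("n_events" in p for p in validate_recording(tiny_recording))


class TestWriteRead:
    def test_tiny_recording_three_files_row_count(self, tiny_recording, tmp_path):
        paths = write_recording(tiny_recording, tmp_path / "rec")
        assert len(paths) == 3
        data_lines = [
            l for l in paths[0].read_text().splitlines() if not l.startswith("#")
        ]
        assert len(data_lines) == 1 + 3  # header + one row per sample

    def test_round_trip_identity(self, tiny_recording, tmp_path):
        write_recording(tiny_recording, tmp_path / "rec")
        assert read_recording(tmp_path / "rec") == tiny_recording

    def test_empty_recording_round_trips(self, tmp_path):
        empty = Recording([], RecordingMeta())
        paths = write_recording(empty, tmp_path / "rec")
        assert all(p.exists() for p in paths)
        assert read_recording(tmp_path / "rec") == empty

    def test_optional_columns_absent_not_zero(self, rng, tmp_path):
        rec = make_recording(rng, with_raw=False, with_temp=False)
        write_recording(rec, tmp_path / "rec")
        back = read_recording(tmp_path / "rec")
        for e in back.iter_events():
            assert e.raw is None and e.temperature is None

    def test_invalid_recording_refused_with_offender_named(self, rng, tmp_path):
        rec = make_recording(rng, n_blocks=1)
        rec.blocks[0].events[0].sample_ids += 1
        with pytest.raises(ValidationError, match="sample_ids not contiguous"):
            write_recording(rec, tmp_path / "rec")
        assert not (tmp_path / "rec.data.tsv").exists()

    def test_sample_id_gap_in_file_rejected(self, rng, tmp_path):
        rec = make_recording(rng, n_blocks=1)
        data, _, _ = write_recording(rec, tmp_path / "rec")
        lines = data.read_text().splitlines()
        # corrupt the last data row's sample_id
        parts = lines[-1].split("\t")
        parts[0] = str(int(parts[0]) + 10)
        lines[-1] = "\t".join(parts)
        data.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError, match="not contiguous"):
            read_recording(tmp_path / "rec")

    def test_malformed_row_raises_parse_error(self, rng, tmp_path):
        rec = make_recording(rng, n_blocks=1)
        data, _, _ = write_recording(rec, tmp_path / "rec")
        lines = data.read_text().splitlines()
        parts = lines[-1].split("\t")
        parts[0] = "not-an-id"
        lines[-1] = "\t".join(parts)
        data.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError):
            read_recording(tmp_path / "rec")

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_recording(tmp_path / "absent")

    def test_metadata_round_trips_configs(self, rng, tmp_path):
        rec = make_recording(rng, n_blocks=1)
        rec.meta.protocol = ProtocolConfig(
            mode="external_trigger", event_samples=rec.blocks[0].events[0].n_samples
        )
        rec.blocks[0].events = rec.blocks[0].events[:1]
        rec.meta.n_events = 1
        n = rec.blocks[0].events[0].n_samples
        if rec.timestamps is not None:
            rec.timestamps = rec.timestamps[:n]
            rec.markers = rec.markers[:n]
        write_recording(rec, tmp_path / "rec")
        back = read_recording(tmp_path / "rec")
        assert back.meta.protocol == rec.meta.protocol
        assert back.meta.hardware == rec.meta.hardware
        assert back.meta.subject == rec.meta.subject

    @settings(max_examples=40)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_round_trip_identity_property(self, seed, tmp_path_factory):
        """write -> read is the identity for randomly generated valid recordings."""
        rec = make_recording(np.random.default_rng(seed))
        base = tmp_path_factory.mktemp("rt") / "rec"
        write_recording(rec, base)
        assert read_recording(base) == rec

    def test_timestamp_row_count_matches_samples(self, rng, tmp_path):
        rec = make_recording(rng, with_timestamps=True)
        _, time_path, _ = write_recording(rec, tmp_path / "rec")
        rows = [
            l for l in time_path.read_text().splitlines() if not l.startswith("#")
        ]
        assert len(rows) - 1 == rec.n_samples

    def test_export_csv_row_count(self, random_recording, tmp_path):
        path = export_csv(random_recording, tmp_path / "flat.csv")
        assert sum(1 for _ in open(path)) == random_recording.n_samples + 1


class TestSampleView:
    def test_samples_iterator_matches_arrays(self, tiny_recording):
        event = tiny_recording.blocks[0].events[0]
        samples = list(event.samples())
        assert [s.sample_id for s in samples] == [0, 1, 2]
        assert samples[0].a == (0.0, 0.0, 9.81)
        assert samples[0].raw is None and samples[0].temperature is None
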