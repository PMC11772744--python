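"""SNIRF container I/O: round trips, integrity failures, single-run rule."""

import h5py
import numpy as np
import pytest

from nirsbids.model import (
    ChannelDef,
    EventRecord,
    Montage,
    NirsBidsError,
    OptodeDef,
    OptodeRole,
    PositionKind,
)
from nirsbids.snirf import (
    SnirfIntegrityError,
    SnirfMultipleRunsError,
    SnirfReadError,
    SnirfRecording,
    SnirfUnsupportedError,
    extract_sidecar_seed,
    read_snirf,
    write_snirf,
)
from nirsbids.synth import MontageSpec, StudySpec, TaskSpec, generate_recording, replica_spec


def _tiny_recording(n_samples=10, coordinate_kind="measured3d", with_aux=False, seed=0):
    rng = np.random.default_rng(seed)
    position = {
        "measured3d": lambda k: (float(k), 0.0, 50.0),
        "template2d": lambda k: (float(k), 0.0),
        "absent": lambda k: None,
    }[coordinate_kind]
    montage = Montage(
        optodes=[
            OptodeDef("S1", OptodeRole.SOURCE, position=position(0)),
            OptodeDef("D1", OptodeRole.DETECTOR, position=position(1)),
            OptodeDef("D2", OptodeRole.DETECTOR, position=position(2)),
        ],
        channels=[
            ChannelDef("S1_D1 760nm", "S1", "D1", 760.0, 10.0),
            ChannelDef("S1_D1 850nm", "S1", "D1", 850.0, 10.0),
            ChannelDef("S1_D2 760nm", "S1", "D2", 760.0, 10.0, short_channel=True),
            ChannelDef("S1_D2 850nm", "S1", "D2", 850.0, 10.0, short_channel=True),
        ],
        coordinate_frame="custom" if coordinate_kind != "absent" else None,
    )
    time = np.arange(n_samples) / 10.0
    data = rng.uniform(0.5, 1.5, size=(n_samples, 4))
    aux = []
    if with_aux:
        aux = [
            ("accel_x", time, rng.normal(size=n_samples), "g"),
            ("accel_y", time, rng.normal(size=n_samples), "g"),
        ]
    stims = [
        ("left", [EventRecord(0.1, 0.2, "left", value=1.0)]),
        ("right", [EventRecord(0.5, 0.2, "right", value=2.0)]),
    ]
    return SnirfRecording(
        time=time,
        data=data,
        montage=montage,
        stims=stims,
        aux=aux,
        meta={"SubjectID": "01", "MeasurementDate": "2023-06-15", "CustomTag": "kept"},
    )


def _assert_recordings_equal(a: SnirfRecording, b: SnirfRecording):
    np.testing.assert_array_equal(a.time, b.time)
    np.testing.assert_array_equal(a.data, b.data)
    assert a.meta == b.meta
    assert a.montage.coordinate_frame == b.montage.coordinate_frame
    assert a.montage.unit == b.montage.unit
    assert [(o.label, o.role, o.position) for o in a.montage.optodes] == [
        (o.label, o.role, o.position) for o in b.montage.optodes
    ]
    assert len(a.montage.channels) == len(b.montage.channels)
    for ch_a, ch_b in zip(a.montage.channels, b.montage.channels):
        assert (ch_a.name, ch_a.source_label, ch_a.detector_label) == (
            ch_b.name, ch_b.source_label, ch_b.detector_label
        )
        assert ch_a.wavelength_nominal == ch_b.wavelength_nominal
        assert ch_a.short_channel == ch_b.short_channel
        # the reader re-derives the rate from the time vector
        assert ch_b.sampling_frequency == pytest.approx(ch_a.sampling_frequency, rel=1e-6)
    assert len(a.stims) == len(b.stims)
    for (name_a, evs_a), (name_b, evs_b) in zip(a.stims, b.stims):
        assert name_a == name_b and evs_a == evs_b
    assert len(a.aux) == len(b.aux)
    for (na, ta, va, ua), (nb_, tb, vb, ub) in zip(a.aux, b.aux):
        assert na == nb_ and ua == ub
        np.testing.assert_array_equal(ta, tb)
        np.testing.assert_array_equal(va, vb)


class TestRoundTrip:
    @pytest.mark.parametrize("kind", ["measured3d", "template2d", "absent"])
    def test_write_read_identity_over_position_kinds(self, tmp_path, kind):
        rec = _tiny_recording(coordinate_kind=kind, with_aux=True)
        path = tmp_path / "rec.snirf"
        write_snirf(rec, path)
        _assert_recordings_equal(rec, read_snirf(path))

    @pytest.mark.parametrize("seed", range(8))
    def test_write_read_identity_fuzzed(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        spec = StudySpec(
            name="fuzz",
            n_participants=1,
            montage_spec=MontageSpec(
                int(rng.integers(1, 4)),
                int(rng.integers(1, 4)),
                int(rng.integers(1, 5)),
                int(rng.integers(0, 3)),
                coordinate_kind=str(rng.choice(["measured3d", "template2d", "absent"])),
            ),
            task_spec=TaskSpec(name="t", conditions=("a",), block_duration_s=2,
                               inter_block_interval_s=1, n_blocks_per_condition=1),
            fs=float(rng.uniform(4, 9)),
            seed=seed,
        )
        rec = generate_recording(spec, 0)
        path = tmp_path / "rec.snirf"
        write_snirf(rec, path)
        _assert_recordings_equal(rec, read_snirf(path))

    def test_minimal_one_channel_recording(self, tmp_path):
        montage = Montage(
            optodes=[OptodeDef("S1", OptodeRole.SOURCE), OptodeDef("D1", OptodeRole.DETECTOR)],
            channels=[ChannelDef("S1_D1 760nm", "S1", "D1", 760.0, 10.0),
                      ChannelDef("S1_D1 850nm", "S1", "D1", 850.0, 10.0)],
        )
        rec = SnirfRecording(
            time=np.arange(10) / 10.0, data=np.ones((10, 2)), montage=montage
        )
        path = tmp_path / "min.snirf"
        write_snirf(rec, path)
        _assert_recordings_equal(rec, read_snirf(path))

    def test_aux_series_count_preserved(self, tmp_path):
        rec = _tiny_recording(with_aux=True)
        path = tmp_path / "aux.snirf"
        write_snirf(rec, path)
        with h5py.File(path, "r") as f:
            aux_groups = [k for k in f["nirs"] if k.startswith("aux")]
        assert len(aux_groups) == 2

    def test_three_conditions_become_three_stim_groups(self, tmp_path):
        rec = generate_recording(replica_spec("motor_task"), 0)
        path = tmp_path / "motor.snirf"
        write_snirf(rec, path)
        with h5py.File(path, "r") as f:
            stim_groups = [k for k in f["nirs"] if k.startswith("stim")]
        assert len(stim_groups) == 3

    def test_sampling_frequency_within_one_percent(self, tmp_path):
        rec = _tiny_recording(n_samples=100)
        path = tmp_path / "fs.snirf"
        write_snirf(rec, path)
        fs = read_snirf(path).sampling_frequency
        assert abs(fs - 10.0) <= 0.01 * 10.0


class TestWriterRejections:
    def test_zero_channels_rejected(self, tmp_path):
        rec = _tiny_recording()
        rec.montage.channels = []
        rec.data = rec.data[:, :0]
        with pytest.raises(NirsBidsError, match="at least one channel"):
            write_snirf(rec, tmp_path / "bad.snirf")

    def test_non_monotone_time_rejected(self, tmp_path):
        rec = _tiny_recording()
        rec.time = rec.time[::-1].copy()
        with pytest.raises(NirsBidsError, match="increasing"):
            write_snirf(rec, tmp_path / "bad.snirf")

    def test_negative_amplitudes_rejected(self, tmp_path):
        rec = _tiny_recording()
        rec.data[0, 0] = -1.0
        with pytest.raises(NirsBidsError, match=">= 0"):
            write_snirf(rec, tmp_path / "bad.snirf")


class TestReaderFailures:
    def _write_valid(self, tmp_path):
        path = tmp_path / "rec.snirf"
        write_snirf(_tiny_recording(), path)
        return path

    def test_dangling_wavelength_index(self, tmp_path):
        path = self._write_valid(tmp_path)
        with h5py.File(path, "a") as f:
            del f["nirs/data1/measurementList1/wavelengthIndex"]
            f["nirs/data1/measurementList1"].create_dataset("wavelengthIndex", data=99)
        with pytest.raises(SnirfIntegrityError, match="wavelengthIndex"):
            read_snirf(path)

    def test_second_data_block_refused(self, tmp_path):
        path = self._write_valid(tmp_path)
        with h5py.File(path, "a") as f:
            f.copy("nirs/data1", "nirs/data2")
        with pytest.raises(SnirfMultipleRunsError, match="single run"):
            read_snirf(path)

    def test_second_nirs_group_refused(self, tmp_path):
        path = self._write_valid(tmp_path)
        with h5py.File(path, "a") as f:
            f.copy("nirs", "nirs2")
        with pytest.raises(SnirfMultipleRunsError):
            read_snirf(path)

    def test_missing_probe_group_named_in_error(self, tmp_path):
        path = self._write_valid(tmp_path)
        with h5py.File(path, "a") as f:
            del f["nirs/probe"]
        with pytest.raises(SnirfReadError, match="probe"):
            read_snirf(path)

    def test_time_domain_payload_rejected_not_mangled(self, tmp_path):
        path = self._write_valid(tmp_path)
        with h5py.File(path, "a") as f:
            for k in f["nirs/data1"]:
                if k.startswith("measurementList"):
                    del f[f"nirs/data1/{k}/dataType"]
                    f[f"nirs/data1/{k}"].create_dataset("dataType", data=201)
        with pytest.raises(SnirfUnsupportedError, match="not yet supported"):
            read_snirf(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(SnirfReadError, match="no such file"):
            read_snirf(tmp_path / "absent.snirf")


class TestSidecarSeed:
    def test_sampling_frequency_copied(self, small_recording):
        draft = extract_sidecar_seed(small_recording)
        assert draft.nirs_json["SamplingFrequency"] == pytest.approx(5.0, rel=0.01)
        assert draft.nirs_json["TaskName"] == ""  # study-level, converter fills it

    def test_short_pairs_expand_to_per_wavelength_rows(self):
        spec = StudySpec(
            name="shorts",
            n_participants=1,
            montage_spec=MontageSpec(8, 8, 24, 12, coordinate_kind="template2d"),
            task_spec=TaskSpec(name="t", conditions=("a",), block_duration_s=2,
                               inter_block_interval_s=1, n_blocks_per_condition=1),
            fs=5.0,
        )
        draft = extract_sidecar_seed(generate_recording(spec, 0))
        short_rows = draft.channels_table[draft.channels_table["short_channel"]]
        assert len(short_rows) == 24  # 12 short pairs x 2 wavelengths
        assert draft.nirs_json["ShortChannelCounts"] == 12  # counted per pair

    def test_template_layout_gets_missing_marker_in_z(self, small_recording):
        draft = extract_sidecar_seed(small_recording)
        assert small_recording.montage.position_kind is PositionKind.TEMPLATE_2D
        assert draft.optodes_table["z"].isna().all()


class TestMneCrossCheck:
    """Independent oracle: MNE-Python's SNIRF reader must agree with ours."""

    def test_mne_reads_our_files_identically(self, tmp_path):
        mne = pytest.importorskip("mne")
        rec = generate_recording(replica_spec("motor_task", seed=2), 0)
        path = tmp_path / "motor.snirf"
        write_snirf(rec, path)
        raw = mne.io.read_raw_snirf(path, verbose="ERROR")
        assert len(raw.ch_names) == rec.n_channels
        assert raw.info["sfreq"] == pytest.approx(rec.sampling_frequency, rel=1e-6)
        np.testing.assert_allclose(raw.get_data().T, rec.data)
        annotations = set(raw.annotations.description)
        assert annotations == {name for name, _ in rec.stims}
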