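"""Dataset assembly: layout, sidecar content, redundancy, extras, manifest."""

import json
from dataclasses import replace

import pytest

from nirsbids.convert import (
    StudyDescription,
    attach_extra_data,
    build_dataset,
    write_sidecars,
)
from nirsbids.manifest import ManifestError, load_manifest
from nirsbids.model import NA, BidsEntities, NirsBidsError
from nirsbids.sidecars import read_json, read_tsv, short_pair_count
from nirsbids.snirf import read_snirf, write_snirf
from nirsbids.synth import generate_recording, generate_study, replica_spec


def _study(n, **extra_cols):
    return StudyDescription(
        name="Study",
        authors=["A. Researcher"],
        participants=[
            {"participant_id": f"sub-{i + 1:02d}", **extra_cols} for i in range(n)
        ],
    )


class TestBuildDataset:
    def test_five_subjects_one_run_each(self, tmp_path, small_spec):
        spec = replace(small_spec, n_participants=5)
        runs = [
            (generate_recording(spec, i), BidsEntities(subject=f"{i + 1:02d}", task="task"))
            for i in range(5)
        ]
        summary = build_dataset(runs, _study(5), tmp_path / "ds")
        root = tmp_path / "ds"
        sub_dirs = sorted(d.name for d in root.iterdir() if d.name.startswith("sub-"))
        assert sub_dirs == [f"sub-{i + 1:02d}" for i in range(5)]
        assert all((root / d / "nirs").is_dir() for d in sub_dirs)
        assert len(read_tsv(root / "participants.tsv")) == 5
        assert summary.n_runs == 5 and len(summary.subjects) == 5

    def test_two_sessions_nest_under_subject(self, tmp_path, small_recording):
        runs = [
            (small_recording, BidsEntities(subject="01", task="task", session="01")),
            (small_recording, BidsEntities(subject="01", task="task", session="02")),
        ]
        build_dataset(runs, _study(1), tmp_path / "ds")
        assert (tmp_path / "ds/sub-01/ses-01/nirs").is_dir()
        assert (tmp_path / "ds/sub-01/ses-02/nirs").is_dir()
        name = "sub-01_ses-01_task-task_nirs.snirf"
        assert (tmp_path / "ds/sub-01/ses-01/nirs" / name).exists()

    def test_zero_runs_rejected(self, tmp_path):
        with pytest.raises(NirsBidsError, match="at least one run"):
            build_dataset([], _study(1), tmp_path / "ds")

    def test_duplicate_entity_tuples_rejected(self, tmp_path, small_recording):
        runs = [
            (small_recording, BidsEntities(subject="01", task="task")),
            (small_recording, BidsEntities(subject="01", task="task")),
        ]
        with pytest.raises(NirsBidsError, match="duplicate"):
            build_dataset(runs, _study(1), tmp_path / "ds")

    def test_subject_missing_from_roster_rejected_by_default(self, tmp_path, small_recording):
        runs = [(small_recording, BidsEntities(subject="99", task="task"))]
        with pytest.raises(NirsBidsError, match="missing from participants"):
            build_dataset(runs, _study(1), tmp_path / "ds")
        build_dataset(runs, _study(1), tmp_path / "ds2", auto_add_participants=True)
        roster = read_tsv(tmp_path / "ds2/participants.tsv")
        assert "sub-99" in set(roster["participant_id"])

    def test_nonempty_root_rejected(self, tmp_path, small_recording):
        root = tmp_path / "ds"
        root.mkdir()
        (root / "leftover.txt").write_text("x")
        with pytest.raises(NirsBidsError, match="not empty"):
            build_dataset(
                [(small_recording, BidsEntities(subject="01", task="task"))],
                _study(1),
                root,
            )

    def test_conversion_is_idempotent_bytewise(self, tmp_path, small_spec):
        roots = []
        for k in range(2):
            root = tmp_path / f"ds{k}"
            generate_study(small_spec, root)
            roots.append(root)
        files_a = sorted(p.relative_to(roots[0]) for p in roots[0].rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(roots[1]) for p in roots[1].rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (roots[0] / rel).read_bytes() == (roots[1] / rel).read_bytes(), rel


class TestWriteSidecars:
    def test_template_layout_z_column_is_all_na(self, tmp_path, small_recording):
        _, paths = write_sidecars(
            small_recording, BidsEntities(subject="01", task="task"), tmp_path
        )
        optodes = read_tsv(tmp_path / "sub-01_task-task_optodes.tsv")
        assert (optodes["z"] == NA).all()

    def test_no_events_file_without_stimulus_blocks(self, tmp_path, small_recording):
        small_recording.stims = []
        _, paths = write_sidecars(
            small_recording, BidsEntities(subject="01", task="task"), tmp_path
        )
        assert not any("events" in p.name for p in paths)

    def test_motor_replica_events_have_three_trial_types(self, tmp_path):
        rec = generate_recording(replica_spec("motor_task"), 0)
        write_sidecars(rec, BidsEntities(subject="01", task="tapping"), tmp_path)
        events = read_tsv(tmp_path / "sub-01_task-tapping_events.tsv")
        assert events["trial_type"].nunique() == 3

    def test_positions_without_coordinate_frame_rejected(self, tmp_path, small_recording):
        small_recording.montage.coordinate_frame = None
        with pytest.raises(NirsBidsError, match="coordinate"):
            write_sidecars(small_recording, BidsEntities(subject="01", task="task"), tmp_path)

    def test_emitted_files_parse_back_to_equal_documents(self, tmp_path, small_recording):
        entities = BidsEntities(subject="01", task="task")
        sidecars, paths = write_sidecars(small_recording, entities, tmp_path)
        nirs_json = read_json(tmp_path / "sub-01_task-task_nirs.json")
        assert nirs_json == json.loads(json.dumps(sidecars.nirs_json))
        channels = read_tsv(tmp_path / "sub-01_task-task_channels.tsv")
        assert len(channels) == len(sidecars.channels_table)
        assert list(channels["name"]) == list(sidecars.channels_table["name"])

    def test_controlled_redundancy_matches_snirf_content(self, small_tree):
        snirf_path = next(small_tree.glob("sub-01/nirs/*_nirs.snirf"))
        rec = read_snirf(snirf_path)
        nirs_json = read_json(next(small_tree.glob("sub-01/nirs/*_nirs.json")))
        channels = read_tsv(next(small_tree.glob("sub-01/nirs/*_channels.tsv")))
        assert nirs_json["NIRSChannelCount"] == rec.n_channels == len(channels)
        assert nirs_json["SamplingFrequency"] == pytest.approx(rec.sampling_frequency, rel=0.01)
        assert nirs_json["NIRSSourceOptodeCount"] == len(rec.montage.sources())
        assert nirs_json["NIRSDetectorOptodeCount"] == len(rec.montage.detectors())
        assert nirs_json["ShortChannelCounts"] == len(rec.montage.short_pairs())
        assert short_pair_count(channels) == len(rec.montage.short_pairs())


class TestAttachExtraData:
    def test_vendor_file_lands_untouched_in_sourcedata(self, small_tree, tmp_path):
        payload = tmp_path / "scan.vendor"
        payload.write_bytes(b"\x00raw vendor bytes")
        dest = attach_extra_data(small_tree, "sourcedata", payload)
        assert dest == small_tree / "sourcedata" / "scan.vendor"
        assert dest.read_bytes() == payload.read_bytes()

    def test_conversion_script_lands_in_code(self, small_tree):
        dest = attach_extra_data(small_tree, "code", "print('convert')\n", dest_name="convert.py")
        assert dest == small_tree / "code" / "convert.py"

    def test_separate_device_heart_rate_routed_outside_snirf(self, small_tree):
        dest = attach_extra_data(
            small_tree, "physio", "time\tbpm\n0\t60\n", subject="01",
            dest_name="sub-01_task-task_physio.tsv",
        )
        assert dest.parent == small_tree / "sub-01" / "physio"
        # nirs content untouched: the SNIRF file still has no aux series
        rec = read_snirf(next(small_tree.glob("sub-01/nirs/*_nirs.snirf")))
        assert rec.aux == []

    def test_injecting_into_snirf_aux_is_refused(self, small_tree):
        with pytest.raises(NirsBidsError, match="physiological-recordings"):
            attach_extra_data(small_tree, "aux", "hr data", subject="01", dest_name="hr.tsv")

    def test_extras_keep_dataset_validator_clean(self, small_tree):
        from nirsbids.validate import validate_dataset

        attach_extra_data(small_tree, "code", "x = 1\n", dest_name="convert.py")
        attach_extra_data(small_tree, "eeg", "not validated here", subject="01", dest_name="notes.txt")
        assert validate_dataset(small_tree) == []


class TestManifest:
    def _write_manifest(self, tmp_path, doc):
        path = tmp_path / "manifest.json"
        path.write_text(json.dumps(doc))
        return path

    def test_valid_manifest_loads(self, tmp_path, small_recording):
        snirf_path = tmp_path / "rec.snirf"
        write_snirf(small_recording, snirf_path)
        path = self._write_manifest(
            tmp_path,
            {
                "name": "Demo",
                "participants": [{"participant_id": "sub-01", "age": 30}],
                "runs": [{"snirf": "rec.snirf", "subject": "01", "task": "task"}],
            },
        )
        manifest = load_manifest(path)
        assert manifest.runs[0].entities() == BidsEntities(subject="01", task="task")

    @pytest.mark.parametrize(
        "doc, loc",
        [
            ({"participants": [], "runs": []}, "name"),
            ({"name": "x", "participants": [{"participant_id": "01"}], "runs": []}, "participant_id"),
            (
                {
                    "name": "x",
                    "participants": [{"participant_id": "sub-01"}],
                    "runs": [{"snirf": "a.snirf", "subject": "01", "task": "t", "bogus": 1}],
                },
                "bogus",
            ),
        ],
    )
    def test_schema_violations_report_field_paths(self, tmp_path, doc, loc):
        path = self._write_manifest(tmp_path, doc)
        with pytest.raises(ManifestError, match=loc):
            load_manifest(path)
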