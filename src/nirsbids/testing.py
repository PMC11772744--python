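"""Testing utilities: a validator mutation suite and a study-spec fuzzer.

The mutation suite corrupts exactly one aspect of a freshly generated
dataset per mutation and declares which rule codes may legitimately flag it.
Datasets passed to it should use a 2-D template layout so the coordinate
mutations apply.  The fuzzer draws small random-but-valid study
configurations (montage sizes, coordinate kinds, session/run presence) for
generator-validator closure checks.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass
from pathlib import Path

import h5py

from .convert import StudyDescription, build_dataset
from .model import BidsEntities
from .sidecars import read_json, read_tsv, write_json, write_tsv
from .synth import MontageSpec, StudySpec, TaskSpec, generate_recording, generate_study


def _one(root: Path, pattern: str) -> Path:
    matches = sorted(Path(root).glob(pattern))
    if not matches:
        raise FileNotFoundError(f"no file matching {pattern} under {root}")
    return matches[0]


def _delete(pattern):
    def apply(root: Path) -> None:
        _one(root, pattern).unlink()

    return apply


def _corrupt_nirs_json(fieldname, value):
    def apply(root: Path) -> None:
        path = _one(root, "sub-*/nirs/*_nirs.json")
        doc = read_json(path)
        doc[fieldname] = value(doc[fieldname]) if callable(value) else value
        write_json(doc, path)

    return apply


def _collapse_channels_per_pair(root: Path) -> None:
    """Rewrite channels.tsv with one row per source-detector pair, the way a
    per-pair (rather than per-wavelength) channel definition would look."""
    path = _one(root, "sub-*/nirs/*_channels.tsv")
    table = read_tsv(path)
    table = table.drop_duplicates(subset=["source", "detector"], keep="first")
    write_tsv(table.reset_index(drop=True), path)


def _duplicate_data_block(root: Path) -> None:
    path = _one(root, "sub-*/nirs/*_nirs.snirf")
    with h5py.File(path, "a") as f:
        f.copy("nirs/data1", "nirs/data2")


def _misplace_across_subjects(root: Path) -> None:
    src = _one(root, "sub-01/nirs/*_nirs.snirf")
    dest_dir = _one(root, "sub-02/nirs")
    shutil.copyfile(src, dest_dir / src.name)


def _numeric_template_z(root: Path) -> None:
    path = _one(root, "sub-*/nirs/*_optodes.tsv")
    table = read_tsv(path)
    table["z"] = "0"
    write_tsv(table, path)


def _flip_short_flags(root: Path) -> None:
    path = _one(root, "sub-*/nirs/*_channels.tsv")
    table = read_tsv(path)
    table["short_channel"] = ["false"] * len(table)
    write_tsv(table, path)


def _rewrite_wavelengths(root: Path) -> None:
    path = _one(root, "sub-*/nirs/*_channels.tsv")
    table = read_tsv(path)
    table["wavelength_nominal"] = ["999"] * len(table)
    write_tsv(table, path)


def _stray_root_file(root: Path) -> None:
    (Path(root) / "legacy_vendor_export.dat").write_text("raw vendor bytes\n")


def _bad_filename(root: Path) -> None:
    path = _one(root, "sub-01/nirs/*_channels.tsv")
    path.rename(path.parent / "sub-01_sub-01_channels.tsv")


def _drop_channel_rows(root: Path) -> None:
    path = _one(root, "sub-*/nirs/*_channels.tsv")
    table = read_tsv(path)
    write_tsv(table.iloc[:-1].reset_index(drop=True), path)


@dataclass(frozen=True)
class Mutation:
    """One single-file corruption and the rule codes allowed to flag it."""

    name: str
    expected_codes: tuple
    apply: callable


MUTATIONS = (
    Mutation("delete_dataset_description", ("NB001",), _delete("dataset_description.json")),
    Mutation("delete_participants", ("NB002",), _delete("participants.tsv")),
    Mutation("delete_nirs_json", ("NB103",), _delete("sub-01/nirs/*_nirs.json")),
    Mutation("delete_channels_tsv", ("NB104",), _delete("sub-01/nirs/*_channels.tsv")),
    Mutation("delete_optodes_tsv", ("NB105",), _delete("sub-01/nirs/*_optodes.tsv")),
    Mutation("delete_coordsystem_json", ("NB106",), _delete("sub-01/nirs/*_coordsystem.json")),
    Mutation("delete_events_tsv", ("NB107",), _delete("sub-01/nirs/*_events.tsv")),
    Mutation(
        "corrupt_sampling_frequency",
        ("NB201",),
        _corrupt_nirs_json("SamplingFrequency", lambda fs: fs / 2.0),
    ),
    Mutation("corrupt_channel_count", ("NB202",), _corrupt_nirs_json("NIRSChannelCount", 1)),
    Mutation("corrupt_optode_count", ("NB203",), _corrupt_nirs_json("NIRSSourceOptodeCount", 99)),
    Mutation("corrupt_short_channel_counts", ("NB204",), _corrupt_nirs_json("ShortChannelCounts", 99)),
    Mutation("collapse_channels_to_pairs", ("NB205", "NB202"), _collapse_channels_per_pair),
    Mutation("duplicate_snirf_data_block", ("NB206",), _duplicate_data_block),
    Mutation("misplace_file_across_subjects", ("NB102",), _misplace_across_subjects),
    Mutation("numeric_z_on_template_layout", ("NB302",), _numeric_template_z),
    Mutation("clear_short_channel_column", ("NB204",), _flip_short_flags),
    Mutation("rewrite_channel_wavelengths", ("NB205", "NB207"), _rewrite_wavelengths),
    Mutation("stray_file_at_root", ("NB006",), _stray_root_file),
    Mutation("unparseable_filename", ("NB101",), _bad_filename),
    Mutation("drop_channel_row", ("NB202",), _drop_channel_rows),
)


def small_study_spec(seed: int = 7, coordinate_kind: str = "template2d") -> StudySpec:
    """A fast two-participant study used as the mutation-suite substrate."""
    return StudySpec(
        name="mutation substrate",
        n_participants=2,
        montage_spec=MontageSpec(2, 2, 3, 1, coordinate_kind=coordinate_kind),
        task_spec=TaskSpec(
            name="task",
            conditions=("a", "b"),
            block_duration_s=3.0,
            inter_block_interval_s=2.0,
            n_blocks_per_condition=1,
        ),
        fs=5.0,
        seed=seed,
    )


_WAVELENGTH_POOL = (690.0, 760.0, 808.0, 850.0)
_CONDITION_POOL = ("left", "right", "rest", "speech", "noise")


def fuzz_study_spec(rng, seed: int) -> StudySpec:
    """Draw one small, valid study configuration."""
    n_sources = int(rng.integers(1, 5))
    n_detectors = int(rng.integers(1, 5))
    long_pairs = int(rng.integers(1, n_sources * n_detectors + 1))
    short_pairs = int(rng.integers(0, 4))
    n_wl = int(rng.integers(2, 4))
    wavelengths = tuple(sorted(rng.choice(_WAVELENGTH_POOL, size=n_wl, replace=False)))
    kind = str(rng.choice(["measured3d", "template2d", "absent"]))
    n_cond = int(rng.integers(1, 4))
    conditions = tuple(rng.choice(_CONDITION_POOL, size=n_cond, replace=False))
    return StudySpec(
        name="fuzzed study",
        n_participants=int(rng.integers(1, 4)),
        montage_spec=MontageSpec(
            n_sources, n_detectors, long_pairs, short_pairs,
            wavelengths=wavelengths, coordinate_kind=kind,
        ),
        task_spec=TaskSpec(
            name="fuzz",
            conditions=conditions,
            block_duration_s=float(rng.uniform(2.0, 5.0)),
            inter_block_interval_s=float(rng.uniform(1.0, 4.0)),
            n_blocks_per_condition=int(rng.integers(1, 3)),
        ),
        fs=float(rng.uniform(4.0, 8.0)),
        seed=seed,
    )


def generate_fuzzed_dataset(rng, root, seed: int) -> StudySpec:
    """Build one fuzzed dataset at ``root``, sometimes with sessions or runs."""
    spec = fuzz_study_spec(rng, seed)
    layout = rng.random()
    if layout < 0.5:
        generate_study(spec, root)
        return spec
    # exercise session/run entities through the converter directly
    use_sessions = layout < 0.75
    participants = [
        {"participant_id": f"sub-{i + 1:02d}"} for i in range(spec.n_participants)
    ]
    study = StudyDescription(name=spec.name, authors=["fuzzer"], participants=participants)
    runs = []
    for i in range(spec.n_participants):
        rec = generate_recording(spec, i)
        subject = f"{i + 1:02d}"
        if use_sessions:
            runs.append((rec, BidsEntities(subject=subject, task="fuzz", session="01")))
            runs.append((rec, BidsEntities(subject=subject, task="fuzz", session="02")))
        else:
            runs.append((rec, BidsEntities(subject=subject, task="fuzz", run=1)))
            runs.append((rec, BidsEntities(subject=subject, task="fuzz", run=2)))
    build_dataset(runs, study, root)
    return spec
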