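"""Assemble recordings plus study metadata into a NIRS-BIDS directory tree.

The layout produced is the standard BIDS hierarchy::

    <root>/
      dataset_description.json
      participants.tsv
      sub-<label>/[ses-<label>/]nirs/
        sub-<label>[_ses-<label>][_run-<k>]_task-<label>_nirs.snirf
        ..._nirs.json  ..._channels.tsv  [..._optodes.tsv  ..._coordsystem.json]
        [..._events.tsv]
      [sourcedata/  code/  stimuli/]

Sidecar values are derived from the SNIRF content itself (controlled
redundancy), so converter output and file content agree by construction.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .model import BidsEntities, NirsBidsError, PositionKind, format_bids_basename
from .sidecars import SidecarSet, write_json, write_tsv
from .snirf import SnirfRecording, extract_sidecar_seed, write_snirf

BIDS_VERSION = "1.8.0"  # the release in which the NIRS data type was merged


@dataclass
class StudyDescription:
    """Study-level metadata: dataset description plus the participant roster.

    ``participants`` rows are mappings with at least ``participant_id``
    (including the ``sub-`` prefix); optional demographic columns such as
    ``age`` and ``sex`` pass through to ``participants.tsv`` unvalidated.
    """

    name: str
    authors: list = field(default_factory=list)
    bids_version: str = BIDS_VERSION
    acknowledgements: Optional[str] = None
    participants: list = field(default_factory=list)
    generated_by: Optional[list] = None

    def participant_ids(self) -> list:
        return [row["participant_id"] for row in self.participants]

    def validate(self) -> None:
        ids = self.participant_ids()
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NirsBidsError(f"participants listed more than once: {dup}")
        for pid in ids:
            if not pid.startswith("sub-"):
                raise NirsBidsError(
                    f"participant_id {pid!r} must carry the 'sub-' prefix"
                )


@dataclass
class DatasetSummary:
    """What :func:`build_dataset` wrote: file list (root-relative), subjects, runs."""

    root: Path
    files: list
    subjects: list
    n_runs: int


def dataset_description_doc(study: StudyDescription) -> dict:
    doc = {"Name": study.name, "BIDSVersion": study.bids_version}
    if study.authors:
        doc["Authors"] = list(study.authors)
    if study.acknowledgements:
        doc["Acknowledgements"] = study.acknowledgements
    if study.generated_by:
        doc["GeneratedBy"] = list(study.generated_by)
    return doc


def participants_frame(study: StudyDescription) -> pd.DataFrame:
    columns = ["participant_id"]
    for row in study.participants:
        for key in row:
            if key not in columns:
                columns.append(key)
    rows = [{c: row.get(c) for c in columns} for row in study.participants]
    return pd.DataFrame(rows, columns=columns)


def write_sidecars(
    rec: SnirfRecording,
    entities: BidsEntities,
    out_dir,
    extra_nirs_json: Optional[dict] = None,
):
    """Emit the sidecar files for one run into ``out_dir``.

    ``*_nirs.json`` and ``*_channels.tsv`` are always written;
    ``*_optodes.tsv`` + ``*_coordsystem.json`` only when the montage carries
    positions; ``*_events.tsv`` only when the run has stimulus blocks.
    Returns ``(SidecarSet, [written Paths])``.
    """
    if rec.montage.position_kind is not PositionKind.ABSENT and not rec.montage.coordinate_frame:
        raise NirsBidsError(
            "optode positions are present but the montage declares no coordinate "
            "frame; set Montage.coordinate_frame (e.g. 'MNI152NLin6Sym' or 'custom')"
        )
    sidecars = extract_sidecar_seed(rec)
    sidecars.nirs_json["TaskName"] = entities.task
    if extra_nirs_json:
        sidecars.nirs_json.update(extra_nirs_json)
    sidecars.validate()

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    path = out_dir / format_bids_basename(entities, "nirs", extension=".json")
    write_json(sidecars.nirs_json, path)
    written.append(path)

    path = out_dir / format_bids_basename(entities, "channels")
    write_tsv(sidecars.channels_table, path)
    written.append(path)

    if sidecars.optodes_table is not None:
        path = out_dir / format_bids_basename(entities, "optodes")
        write_tsv(sidecars.optodes_table, path)
        written.append(path)
        path = out_dir / format_bids_basename(entities, "coordsystem")
        write_json(sidecars.coordsystem, path)
        written.append(path)

    if sidecars.events_table is not None:
        path = out_dir / format_bids_basename(entities, "events")
        write_tsv(sidecars.events_table, path)
        written.append(path)

    return sidecars, written


def run_directory(root, entities: BidsEntities) -> Path:
    d = Path(root) / f"sub-{entities.subject}"
    if entities.session is not None:
        d = d / f"ses-{entities.session}"
    return d / "nirs"


def build_dataset(
    runs,
    study: StudyDescription,
    root,
    auto_add_participants: bool = False,
) -> DatasetSummary:
    """Write a complete NIRS-BIDS tree for ``runs`` = [(SnirfRecording, BidsEntities)].

    ``root`` must be absent or an empty directory.  Every run subject must
    appear in the study's participant roster unless ``auto_add_participants``
    is set, in which case missing subjects are appended with no demographics.
    """
    root = Path(root)
    if root.exists() and any(root.iterdir()):
        raise NirsBidsError(f"output root {root} exists and is not empty")
    if not runs:
        raise NirsBidsError("a dataset must contain at least one run")

    keys = [
        (e.subject, e.session, e.task, e.run)
        for _, e in runs
    ]
    if len(keys) != len(set(keys)):
        dup = sorted({k for k in keys if keys.count(k) > 1})
        raise NirsBidsError(f"duplicate run entity tuples: {dup}")

    study.validate()
    roster = set(study.participant_ids())
    missing = sorted({f"sub-{e.subject}" for _, e in runs} - roster)
    if missing:
        if not auto_add_participants:
            raise NirsBidsError(
                f"subjects present in runs but missing from participants: {missing}"
            )
        study = StudyDescription(
            name=study.name,
            authors=study.authors,
            bids_version=study.bids_version,
            acknowledgements=study.acknowledgements,
            participants=list(study.participants) + [{"participant_id": m} for m in missing],
            generated_by=study.generated_by,
        )

    root.mkdir(parents=True, exist_ok=True)
    written = []

    path = root / "dataset_description.json"
    write_json(dataset_description_doc(study), path)
    written.append(path)

    path = root / "participants.tsv"
    write_tsv(participants_frame(study), path)
    written.append(path)

    subjects = []
    for rec, entities in runs:
        if entities.subject not in subjects:
            subjects.append(entities.subject)
        nirs_dir = run_directory(root, entities)
        nirs_dir.mkdir(parents=True, exist_ok=True)
        snirf_path = nirs_dir / format_bids_basename(entities, "nirs")
        write_snirf(rec, snirf_path)
        written.append(snirf_path)
        _, sidecar_paths = write_sidecars(rec, entities, nirs_dir)
        written.extend(sidecar_paths)

    rel = sorted(p.relative_to(root).as_posix() for p in written)
    return DatasetSummary(root=root, files=rel, subjects=subjects, n_runs=len(runs))


#: Kinds routed to dataset-root subdirectories.
ROOT_EXTRA_KINDS = ("sourcedata", "code", "stimuli")

#: Kinds that would smuggle separate-device recordings into the SNIRF aux
#: group; refused with a pointer to the proper convention.
_FORBIDDEN_EXTRA_KINDS = ("aux", "snirf-aux", "nirs")


def attach_extra_data(
    root,
    kind: str,
    payload,
    subject: Optional[str] = None,
    dest_name: Optional[str] = None,
) -> Path:
    """Place non-NIRS payloads in the tree without touching ``nirs`` content.

    ``kind`` is ``sourcedata``/``code``/``stimuli`` (dataset-root folders) or
    a sibling modality directory name such as ``eeg`` or ``physio`` (requires
    ``subject``).  ``payload`` is a file to copy, or text content when
    ``dest_name`` names the file to create.  Continuous recordings from a
    *separate* device are never injected into an already-written SNIRF aux
    group; pass them as their own modality files instead.
    """
    root = Path(root)
    if not root.exists():
        raise NirsBidsError(f"dataset root {root} does not exist")
    kind = kind.lower()
    if kind in _FORBIDDEN_EXTRA_KINDS:
        raise NirsBidsError(
            f"refusing to add payload as {kind!r}: data recorded with a separate "
            "device must be organized per the BIDS physiological-recordings "
            "convention (its own modality files), not saved into the SNIRF aux "
            "group of an already-written run"
        )
    if kind in ROOT_EXTRA_KINDS:
        dest_dir = root / kind
    else:
        if not kind.isalnum():
            raise NirsBidsError(f"invalid extra-data kind {kind!r}")
        if subject is None:
            raise NirsBidsError(f"modality payloads ({kind!r}) require a subject label")
        dest_dir = root / f"sub-{subject}" / kind
    dest_dir.mkdir(parents=True, exist_ok=True)

    src = Path(payload) if not isinstance(payload, bytes) else None
    if src is not None and src.exists() and src.is_file():
        dest = dest_dir / (dest_name or src.name)
        shutil.copyfile(src, dest)
        return dest
    if dest_name is None:
        raise NirsBidsError("dest_name is required when payload is inline content")
    dest = dest_dir / dest_name
    if isinstance(payload, bytes):
        dest.write_bytes(payload)
    else:
        dest.write_text(str(payload), encoding="utf-8")
    return dest
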