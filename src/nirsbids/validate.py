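"""Rule-based validation of an on-disk NIRS-BIDS dataset.

Severity follows the language of the standard: required content ("must")
raises ERROR, recommended content ("should") raises WARNING.  The events
file is required only when the SNIRF file itself holds stimulus blocks.
Rule codes are namespaced: NB0xx dataset level, NB1xx naming/placement,
NB2xx SNIRF/sidecar redundancy, NB3xx coordinates.

Validation is read-only and deterministic: identical trees yield identical
issue lists (sorted by path, then code).  Non-NIRS sibling modality
directories (e.g. ``eeg/``) coexist but are not validated here.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .model import (
    NA,
    BidsNameError,
    PositionKind,
    Severity,
    ValidationIssue,
    parse_bids_basename,
)
from .sidecars import (
    REQUIRED_NIRS_JSON_FIELDS,
    read_json,
    read_tsv,
    short_pair_count,
)
from .snirf import SnirfMultipleRunsError, read_snirf


@dataclass(frozen=True)
class Rule:
    code: str
    severity: Severity
    description: str
    scope: str  # dataset | subject | run | file


_RULES = [
    Rule("NB000", Severity.ERROR, "dataset root unreadable", "dataset"),
    Rule("NB001", Severity.ERROR, "missing required dataset_description.json", "dataset"),
    Rule("NB002", Severity.ERROR, "missing required participants.tsv", "dataset"),
    Rule("NB003", Severity.ERROR, "dataset_description.json malformed or missing required fields", "dataset"),
    Rule("NB004", Severity.ERROR, "participants.tsv malformed or subject missing from roster", "dataset"),
    Rule("NB005", Severity.WARNING, "participant listed in roster has no subject directory", "dataset"),
    Rule("NB006", Severity.ERROR, "stray file; non-BIDS data belongs in sourcedata/ or code/", "file"),
    Rule("NB007", Severity.ERROR, "dataset contains no NIRS runs", "dataset"),
    Rule("NB101", Severity.ERROR, "filename does not follow the BIDS naming pattern", "file"),
    Rule("NB102", Severity.ERROR, "filename entities disagree with directory placement", "file"),
    Rule("NB103", Severity.ERROR, "missing required *_nirs.json sidecar", "run"),
    Rule("NB104", Severity.ERROR, "missing required *_channels.tsv sidecar", "run"),
    Rule("NB105", Severity.WARNING, "missing recommended *_optodes.tsv", "run"),
    Rule("NB106", Severity.ERROR, "*_optodes.tsv present without its *_coordsystem.json", "run"),
    Rule("NB107", Severity.ERROR, "stimulus blocks present but *_events.tsv missing", "run"),
    Rule("NB108", Severity.WARNING, "*_coordsystem.json present without *_optodes.tsv", "run"),
    Rule("NB109", Severity.ERROR, "sidecar files present but *_nirs.snirf data file missing", "run"),
    Rule("NB110", Severity.WARNING, "*_events.tsv present but SNIRF holds no stimulus blocks", "run"),
    Rule("NB201", Severity.ERROR, "SamplingFrequency disagrees with the SNIRF time vector", "run"),
    Rule("NB202", Severity.ERROR, "channel count disagrees between SNIRF, channels.tsv and NIRSChannelCount", "run"),
    Rule("NB203", Severity.ERROR, "optode counts disagree between SNIRF and sidecars", "run"),
    Rule("NB204", Severity.ERROR, "short-channel bookkeeping disagrees (short_channel column / ShortChannelCounts)", "run"),
    Rule("NB205", Severity.ERROR, "channels must be listed per wavelength of each source-detector pair", "run"),
    Rule("NB206", Severity.ERROR, "SNIRF file holds more than one run", "run"),
    Rule("NB207", Severity.ERROR, "nominal wavelengths disagree between SNIRF and channels.tsv", "run"),
    Rule("NB208", Severity.ERROR, "SNIRF file unreadable or outside the CW subset", "run"),
    Rule("NB209", Severity.ERROR, "required *_nirs.json field missing or of wrong type", "run"),
    Rule("NB210", Severity.ERROR, "events table disagrees with SNIRF stimulus blocks", "run"),
    Rule("NB301", Severity.ERROR, "optode coordinate neither numeric nor the n/a marker", "file"),
    Rule("NB302", Severity.WARNING, "numeric z coordinate on a 2-D template layout; should be n/a", "file"),
    Rule("NB303", Severity.ERROR, "optodes table disagrees with the SNIRF probe", "run"),
    Rule("NB304", Severity.ERROR, "events table malformed", "file"),
]

RULE_CATALOGUE = {rule.code: rule for rule in _RULES}

_ALLOWED_ROOT_FILES = {
    "dataset_description.json",
    "participants.tsv",
    "participants.json",
    "README",
    "README.md",
    "README.txt",
    "CHANGES",
    "LICENSE",
    ".bidsignore",
}
_ALLOWED_ROOT_DIRS = {"sourcedata", "code", "derivatives", "stimuli"}

_SUB_DIR_RE = re.compile(r"^sub-([a-zA-Z0-9]+)$")
_SES_DIR_RE = re.compile(r"^ses-([a-zA-Z0-9]+)$")


def _issue(code: str, path, message: str) -> ValidationIssue:
    return ValidationIssue(
        code=code,
        severity=RULE_CATALOGUE[code].severity,
        path=str(path),
        message=message,
    )


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# focused checks (also usable on their own)
# ---------------------------------------------------------------------------


def check_coordinates(
    optodes_table,
    coordsystem: Optional[dict],
    position_kind: Optional[PositionKind] = None,
    path: str = "optodes.tsv",
) -> list:
    """Check one optodes table (as text cells) against the coordinate rules."""
    issues = []
    if coordsystem is None:
        issues.append(
            _issue("NB106", path, "optodes table has no accompanying coordsystem document")
        )
    for col in ("name", "type", "x", "y", "z"):
        if col not in optodes_table.columns:
            issues.append(_issue("NB301", path, f"optodes table lacks column {col!r}"))
            return issues
    numeric_z = 0
    for row in optodes_table.itertuples(index=False):
        for axis in ("x", "y", "z"):
            cell = getattr(row, axis)
            if cell != NA and not _is_number(cell):
                issues.append(
                    _issue(
                        "NB301",
                        path,
                        f"optode {row.name!r}: {axis} coordinate {cell!r} is neither "
                        f"numeric nor {NA!r}",
                    )
                )
        if _is_number(row.z):
            numeric_z += 1
    if position_kind is PositionKind.TEMPLATE_2D and numeric_z:
        issues.append(
            _issue(
                "NB302",
                path,
                f"{numeric_z} optode rows carry a numeric z coordinate on a 2-D "
                f"template layout; the template z coordinate should be set to {NA!r}",
            )
        )
    return issues


def check_run_consistency(snirf_path, sidecars: dict, rel_dir: str = "") -> list:
    """Cross-check the controlled redundancy between one SNIRF file and its sidecars.

    ``sidecars`` maps sidecar kinds (``nirs_json``, ``channels``, ``optodes``,
    ``coordsystem``, ``events``) to on-disk paths; absent kinds are skipped
    (file-presence rules live in :func:`validate_dataset`).
    """
    issues, _rec = _check_run(snirf_path, sidecars, rel_dir)
    return issues


def _check_run(snirf_path, sidecars: dict, rel_dir: str = ""):
    issues: list = []
    rel = lambda name: f"{rel_dir}/{name}" if rel_dir else name  # noqa: E731
    snirf_rel = rel(Path(snirf_path).name)

    try:
        rec = read_snirf(snirf_path)
    except SnirfMultipleRunsError as exc:
        return [_issue("NB206", snirf_rel, str(exc))], None
    except Exception as exc:  # structured read failures and HDF5 errors alike
        return [_issue("NB208", snirf_rel, str(exc))], None

    montage = rec.montage
    snirf_pairs: dict = {}
    for ch in montage.channels:
        snirf_pairs.setdefault(ch.pair, set()).add(ch.wavelength_nominal)
    snirf_short = montage.short_pairs()

    nirs_json = None
    if "nirs_json" in sidecars:
        jpath = rel(Path(sidecars["nirs_json"]).name)
        try:
            nirs_json = read_json(sidecars["nirs_json"])
        except (json.JSONDecodeError, OSError) as exc:
            issues.append(_issue("NB209", jpath, f"unreadable JSON sidecar: {exc}"))
        if nirs_json is not None:
            for fieldname in REQUIRED_NIRS_JSON_FIELDS:
                if fieldname not in nirs_json:
                    issues.append(
                        _issue("NB209", jpath, f"required field {fieldname!r} missing")
                    )
            fs = nirs_json.get("SamplingFrequency")
            if isinstance(fs, (int, float)) and fs > 0:
                if abs(fs - rec.sampling_frequency) > 0.01 * rec.sampling_frequency:
                    issues.append(
                        _issue(
                            "NB201",
                            jpath,
                            f"redundant metadata mismatch: SamplingFrequency {fs} vs "
                            f"{rec.sampling_frequency:.6g} Hz derived from the SNIRF "
                            "time vector",
                        )
                    )
            elif fs is not None:
                issues.append(_issue("NB209", jpath, "SamplingFrequency must be a positive number"))
            n = nirs_json.get("NIRSChannelCount")
            if isinstance(n, int) and n != rec.n_channels:
                issues.append(
                    _issue(
                        "NB202",
                        jpath,
                        f"redundant metadata mismatch: NIRSChannelCount {n} vs "
                        f"{rec.n_channels} channels in the SNIRF file",
                    )
                )
            for fieldname, actual in (
                ("NIRSSourceOptodeCount", len(montage.sources())),
                ("NIRSDetectorOptodeCount", len(montage.detectors())),
            ):
                v = nirs_json.get(fieldname)
                if isinstance(v, int) and v != actual:
                    issues.append(
                        _issue(
                            "NB203",
                            jpath,
                            f"redundant metadata mismatch: {fieldname} {v} vs {actual}",
                        )
                    )
            scc = nirs_json.get("ShortChannelCounts")
            if isinstance(scc, int) and scc != len(snirf_short):
                issues.append(
                    _issue(
                        "NB204",
                        jpath,
                        f"ShortChannelCounts {scc} vs {len(snirf_short)} short "
                        "source-detector pairs in the SNIRF file",
                    )
                )

    if "channels" in sidecars:
        cpath = rel(Path(sidecars["channels"]).name)
        table = read_tsv(sidecars["channels"])
        required_cols = {"name", "type", "source", "detector", "wavelength_nominal", "short_channel"}
        missing_cols = required_cols - set(table.columns)
        if missing_cols:
            issues.append(
                _issue("NB202", cpath, f"channels table lacks columns {sorted(missing_cols)}")
            )
        else:
            if len(table) != rec.n_channels:
                issues.append(
                    _issue(
                        "NB202",
                        cpath,
                        f"channels table has {len(table)} rows but the SNIRF file "
                        f"has {rec.n_channels} channels (one per wavelength of "
                        "each source-detector pair)",
                    )
                )
            table_pairs: dict = {}
            seen = set()
            for row in table.itertuples(index=False):
                wl = float(row.wavelength_nominal) if _is_number(row.wavelength_nominal) else None
                key = (row.source, row.detector, wl)
                if key in seen:
                    issues.append(
                        _issue(
                            "NB205",
                            cpath,
                            f"duplicate channel row for pair {row.source}-{row.detector} "
                            f"at {row.wavelength_nominal} nm",
                        )
                    )
                seen.add(key)
                if wl is not None:
                    table_pairs.setdefault((row.source, row.detector), set()).add(wl)
            for pair, wls in snirf_pairs.items():
                got = table_pairs.get(pair, set())
                if got != wls and pair in table_pairs:
                    issues.append(
                        _issue(
                            "NB205",
                            cpath,
                            f"pair {pair[0]}-{pair[1]}: channels table lists wavelengths "
                            f"{sorted(got)} but the SNIRF file defines a channel as one "
                            f"wavelength of light, expected {sorted(wls)}",
                        )
                    )
                elif pair not in table_pairs:
                    issues.append(
                        _issue("NB202", cpath, f"pair {pair[0]}-{pair[1]} missing from channels table")
                    )
            snirf_wls = set(montage.wavelengths())
            table_wls = {w for wls in table_pairs.values() for w in wls}
            if table_pairs and table_wls != snirf_wls and all(
                table_pairs.get(p) == wls for p, wls in snirf_pairs.items() if p in table_pairs
            ):
                issues.append(
                    _issue(
                        "NB207",
                        cpath,
                        f"wavelengths {sorted(table_wls)} in channels table vs "
                        f"{sorted(snirf_wls)} in SNIRF probe",
                    )
                )
            table_short = {
                (row.source, row.detector)
                for row in table.itertuples(index=False)
                if str(row.short_channel).lower() in ("true", "1")
            }
            if table_short != snirf_short:
                issues.append(
                    _issue(
                        "NB204",
                        cpath,
                        f"short_channel column flags pairs {sorted(table_short)} but the "
                        f"SNIRF file flags {sorted(snirf_short)}",
                    )
                )

    if "optodes" in sidecars:
        opath = rel(Path(sidecars["optodes"]).name)
        table = read_tsv(sidecars["optodes"])
        coordsystem = None
        if "coordsystem" in sidecars:
            try:
                coordsystem = read_json(sidecars["coordsystem"])
            except (json.JSONDecodeError, OSError) as exc:
                issues.append(
                    _issue("NB106", rel(Path(sidecars["coordsystem"]).name), f"unreadable coordsystem: {exc}")
                )
                coordsystem = {}
        else:
            coordsystem = {}  # presence handled by validate_dataset
        issues.extend(
            i
            for i in check_coordinates(table, coordsystem, montage.position_kind, path=opath)
            if i.code != "NB106"
        )
        if {"name", "type"} <= set(table.columns):
            table_opt = {(row.name, row.type) for row in table.itertuples(index=False)}
            snirf_opt = {(o.label, o.role.value) for o in montage.optodes}
            if montage.position_kind is not PositionKind.ABSENT and table_opt != snirf_opt:
                issues.append(
                    _issue(
                        "NB303",
                        opath,
                        "optode names/roles in the table disagree with the SNIRF probe",
                    )
                )

    if "events" in sidecars:
        epath = rel(Path(sidecars["events"]).name)
        table = read_tsv(sidecars["events"])
        missing_cols = {"onset", "duration", "trial_type"} - set(table.columns)
        if missing_cols:
            issues.append(
                _issue("NB304", epath, f"events table lacks columns {sorted(missing_cols)}")
            )
        else:
            for row in table.itertuples(index=False):
                if not _is_number(row.onset) or float(row.onset) < 0:
                    issues.append(_issue("NB304", epath, f"onset {row.onset!r} must be a number >= 0"))
                    break
                if not _is_number(row.duration) or float(row.duration) < 0:
                    issues.append(_issue("NB304", epath, f"duration {row.duration!r} must be a number >= 0"))
                    break
                if not row.trial_type or row.trial_type == NA:
                    issues.append(_issue("NB304", epath, "trial_type must be non-empty for task events"))
                    break
            snirf_events = rec.events()
            if snirf_events:
                snirf_conditions = {name for name, evs in rec.stims if evs}
                table_conditions = set(table["trial_type"])
                if table_conditions != snirf_conditions:
                    issues.append(
                        _issue(
                            "NB210",
                            epath,
                            f"trial_type values {sorted(table_conditions)} vs SNIRF "
                            f"stimulus conditions {sorted(snirf_conditions)}",
                        )
                    )
                elif len(table) != len(snirf_events):
                    issues.append(
                        _issue(
                            "NB210",
                            epath,
                            f"{len(table)} event rows vs {len(snirf_events)} stimulus "
                            "events in the SNIRF file",
                        )
                    )

    return issues, rec


def check_filenames(root) -> list:
    """Naming/placement pass only (no content checks): every file under the
    subject trees must parse and agree with its directory."""
    issues, _ = _walk_tree(Path(root))
    return [i for i in issues if i.code in ("NB006", "NB101", "NB102")]


# ---------------------------------------------------------------------------
# full dataset validation
# ---------------------------------------------------------------------------


def _walk_tree(root: Path):
    """Collect naming/placement issues and the per-run file groups."""
    issues: list = []
    runs: list = []  # (rel_dir, subject, session, {(suffix, ext): Path})

    for entry in sorted(root.iterdir()):
        name = entry.name
        if entry.is_file():
            if name not in _ALLOWED_ROOT_FILES:
                issues.append(
                    _issue(
                        "NB006",
                        name,
                        "stray file at dataset root; legacy/vendor files belong in sourcedata/",
                    )
                )
            continue
        if entry.is_dir():
            if name in _ALLOWED_ROOT_DIRS:
                continue
            m = _SUB_DIR_RE.match(name)
            if not m:
                issues.append(
                    _issue("NB006", name, "unexpected directory at dataset root")
                )
                continue
            subject = m.group(1)
            ses_dirs = []
            for sub_entry in sorted(entry.iterdir()):
                if sub_entry.is_dir():
                    sm = _SES_DIR_RE.match(sub_entry.name)
                    if sm:
                        ses_dirs.append((sm.group(1), sub_entry))
                    elif sub_entry.name == "nirs":
                        ses_dirs.append((None, entry))
                    elif sub_entry.name.isalnum() and sub_entry.name.islower():
                        continue  # sibling modality directory (eeg, beh, ...)
                    else:
                        issues.append(
                            _issue(
                                "NB006",
                                f"{name}/{sub_entry.name}",
                                "unexpected directory inside subject folder",
                            )
                        )
                else:
                    issues.append(
                        _issue(
                            "NB006",
                            f"{name}/{sub_entry.name}",
                            "unexpected file inside subject folder; non-BIDS data "
                            "belongs in sourcedata/",
                        )
                    )
            for session, parent in ses_dirs:
                nirs_dir = parent / "nirs"
                if not nirs_dir.is_dir():
                    continue
                rel_dir = nirs_dir.relative_to(root).as_posix()
                groups: dict = {}
                for f in sorted(nirs_dir.iterdir()):
                    rel_f = f.relative_to(root).as_posix()
                    if f.is_dir():
                        issues.append(_issue("NB006", rel_f, "unexpected directory inside nirs/"))
                        continue
                    stem = f.name.rsplit(".", 1)[0] if "." in f.name else f.name
                    if stem.endswith("_physio"):
                        continue  # separate-device physiology, validated elsewhere
                    try:
                        entities, suffix = parse_bids_basename(f.name)
                    except BidsNameError as exc:
                        issues.append(_issue("NB101", rel_f, str(exc)))
                        continue
                    if entities.subject != subject or entities.session != session:
                        issues.append(
                            _issue(
                                "NB102",
                                rel_f,
                                f"file entities (sub-{entities.subject}"
                                + (f", ses-{entities.session}" if entities.session else "")
                                + f") do not match directory {rel_dir}",
                            )
                        )
                        continue
                    ext = "." + f.name.rsplit(".", 1)[1] if "." in f.name else ""
                    key = (entities.subject, entities.session, entities.run, entities.task)
                    groups.setdefault(key, {})[(suffix, ext)] = f
                for key, files in sorted(groups.items()):
                    runs.append((rel_dir, subject, session, files))
    return issues, runs


def validate_dataset(root) -> list:
    """Validate a dataset tree; returns all issues, ordered by path then code.

    An empty list means the dataset is fully compliant, recommendations
    included.
    """
    root = Path(root)
    if not root.is_dir():
        return [_issue("NB000", ".", f"dataset root {root} is not a readable directory")]

    issues: list = []

    dd_path = root / "dataset_description.json"
    if not dd_path.exists():
        issues.append(
            _issue("NB001", "dataset_description.json", "every dataset must include a dataset_description.json")
        )
    else:
        try:
            doc = read_json(dd_path)
            for fieldname in ("Name", "BIDSVersion"):
                if not doc.get(fieldname):
                    issues.append(
                        _issue("NB003", "dataset_description.json", f"required field {fieldname!r} missing or empty")
                    )
        except (json.JSONDecodeError, OSError) as exc:
            issues.append(_issue("NB003", "dataset_description.json", f"unreadable JSON: {exc}"))

    roster: Optional[set] = None
    p_path = root / "participants.tsv"
    if not p_path.exists():
        issues.append(
            _issue("NB002", "participants.tsv", "every dataset must include a participants.tsv roster")
        )
    else:
        table = read_tsv(p_path)
        if "participant_id" not in table.columns:
            issues.append(_issue("NB004", "participants.tsv", "missing required column participant_id"))
        else:
            roster = set(table["participant_id"])

    walk_issues, runs = _walk_tree(root)
    issues.extend(walk_issues)

    subjects_seen = {subject for _, subject, _, _ in runs}
    sub_dirs = {
        m.group(1) for e in root.iterdir() if e.is_dir() and (m := _SUB_DIR_RE.match(e.name))
    }
    if not sub_dirs:
        issues.append(_issue("NB007", ".", "dataset contains no subject directories with NIRS data"))
    if roster is not None:
        for subject in sorted(sub_dirs):
            if f"sub-{subject}" not in roster:
                issues.append(
                    _issue("NB004", "participants.tsv", f"sub-{subject} has data but is not listed in participants.tsv")
                )
        for pid in sorted(roster):
            if pid.startswith("sub-") and pid[4:] not in sub_dirs:
                issues.append(
                    _issue("NB005", "participants.tsv", f"{pid} is listed but has no subject directory")
                )

    for rel_dir, subject, session, files in runs:
        snirf_file = files.get(("nirs", ".snirf"))
        sidecars = {}
        if ("nirs", ".json") in files:
            sidecars["nirs_json"] = files[("nirs", ".json")]
        if ("channels", ".tsv") in files:
            sidecars["channels"] = files[("channels", ".tsv")]
        if ("optodes", ".tsv") in files:
            sidecars["optodes"] = files[("optodes", ".tsv")]
        if ("coordsystem", ".json") in files:
            sidecars["coordsystem"] = files[("coordsystem", ".json")]
        if ("events", ".tsv") in files:
            sidecars["events"] = files[("events", ".tsv")]

        some_file = snirf_file or next(iter(files.values()))
        run_tag = some_file.name.rsplit("_", 1)[0]  # entity part of the basename
        if snirf_file is None:
            issues.append(
                _issue("NB109", f"{rel_dir}/{run_tag}_nirs.snirf", "sidecar files present but the SNIRF data file is missing")
            )
            continue
        if "nirs_json" not in sidecars:
            issues.append(
                _issue("NB103", f"{rel_dir}/{run_tag}_nirs.json", "every run must have a *_nirs.json sidecar")
            )
        if "channels" not in sidecars:
            issues.append(
                _issue("NB104", f"{rel_dir}/{run_tag}_channels.tsv", "every run must have a *_channels.tsv sidecar")
            )
        if "optodes" not in sidecars:
            issues.append(
                _issue("NB105", f"{rel_dir}/{run_tag}_optodes.tsv", "recommended optodes table is missing")
            )
            if "coordsystem" in sidecars:
                issues.append(
                    _issue("NB108", f"{rel_dir}/{run_tag}_coordsystem.json", "coordsystem present without an optodes table")
                )
        elif "coordsystem" not in sidecars:
            issues.append(
                _issue(
                    "NB106",
                    f"{rel_dir}/{run_tag}_coordsystem.json",
                    "optodes table present; the paired coordsystem document is required",
                )
            )

        run_issues, rec = _check_run(snirf_file, sidecars, rel_dir=rel_dir)
        issues.extend(run_issues)

        # events required iff the SNIRF holds stimulus blocks
        if rec is not None:
            has_stims = bool(rec.events())
            if has_stims and "events" not in sidecars:
                issues.append(
                    _issue(
                        "NB107",
                        f"{rel_dir}/{run_tag}_events.tsv",
                        "the experimental design includes events; *_events.tsv is required",
                    )
                )
            if not has_stims and "events" in sidecars:
                issues.append(
                    _issue("NB110", f"{rel_dir}/{run_tag}_events.tsv", "events file present but the SNIRF holds no stimulus blocks")
                )

    return sorted(issues, key=lambda i: (i.path, i.code, i.message))


def promote_warnings(issues: list) -> list:
    """Strict mode: every WARNING becomes an ERROR."""
    return [
        ValidationIssue(code=i.code, severity=Severity.ERROR, path=i.path, message=i.message)
        for i in issues
    ]


def error_count(issues: list, strict: bool = False) -> int:
    if strict:
        return len(issues)
    return sum(1 for i in issues if i.severity is Severity.ERROR)
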