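"""Minimal continuous-wave SNIRF (HDF5) reader and writer.

Covers exactly the subset of the SNIRF container needed to carry one BIDS
run: a single ``/nirs`` group with one data block, a probe description,
optional stimulus and auxiliary groups, and free-form ``metaDataTags``.
Files are written with ``formatVersion`` 1.1.

Conventions enforced here:

* only CW amplitude payloads (``dataType`` 1) are handled; time-domain and
  frequency-domain records are detected and rejected, never silently mangled;
* a file holds one run: the writer cannot produce, and the reader refuses,
  files with a second data block or a second ``nirs`` group;
* SNIRF indices are 1-based in-file, all in-memory structures are 0-based —
  the boundary is crossed only inside this module;
* unrecognized ``metaDataTags`` survive a round trip verbatim.

Because SNIRF's measurement list has no short-channel flag, short pair
membership is persisted in the custom tag ``nirsbidsShortChannelPairs``
(SNIRF allows arbitrary string tags); absent the tag, all flags read false.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .model import (
    ChannelDef,
    EventRecord,
    Montage,
    NirsBidsError,
    OptodeDef,
    OptodeRole,
    PositionKind,
    default_channel_name,
)
from .sidecars import (
    SidecarSet,
    channels_table_from_montage,
    coordsystem_from_montage,
    events_table_from_records,
    optodes_table_from_montage,
    short_pair_count,
)

SNIRF_FORMAT_VERSION = "1.1"
CW_AMPLITUDE_DATA_TYPE = 1  # SNIRF dataType code for continuous-wave amplitude

_SHORT_PAIRS_TAG = "nirsbidsShortChannelPairs"

_STR = h5py.string_dtype(encoding="utf-8")


class SnirfError(NirsBidsError):
    """Base class for SNIRF read/write failures."""


class SnirfReadError(SnirfError):
    """A required SNIRF group or dataset is missing or malformed."""


class SnirfIntegrityError(SnirfError):
    """Measurement-list indices dangle beyond the probe arrays."""


class SnirfMultipleRunsError(SnirfError):
    """The file carries more than one run (multiple data blocks or nirs groups)."""


class SnirfUnsupportedError(SnirfError):
    """The file uses a payload outside the CW amplitude subset."""


@dataclass
class SnirfRecording:
    """One continuous-wave run: time base, intensities, probe, events, aux.

    ``data`` has one column per channel of ``montage.channels`` and one row
    per element of ``time``.  ``stims`` maps condition names to event lists,
    ``aux`` holds integrated-device auxiliary series (same device only —
    separate-device physiology belongs in its own BIDS files, not here).
    """

    time: np.ndarray
    data: np.ndarray
    montage: Montage
    stims: list = field(default_factory=list)  # (condition_name, [EventRecord, ...])
    aux: list = field(default_factory=list)  # (name, time, values, unit)
    meta: dict = field(default_factory=dict)  # metaDataTags: name -> text

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.data = np.asarray(self.data, dtype=float)

    def validate(self) -> None:
        self.montage.validate()
        n_ch = len(self.montage.channels)
        if n_ch == 0:
            raise NirsBidsError("recording must have at least one channel")
        if self.data.ndim != 2 or self.data.shape != (self.time.size, n_ch):
            raise NirsBidsError(
                f"data shape {self.data.shape} does not match "
                f"(n_times={self.time.size}, n_channels={n_ch})"
            )
        if self.time.size < 2 or np.any(np.diff(self.time) <= 0):
            raise NirsBidsError("time vector must be strictly increasing with >= 2 samples")
        if not np.all(np.isfinite(self.data)):
            raise NirsBidsError("intensity samples must be finite")
        if np.any(self.data < 0):
            raise NirsBidsError("CW amplitudes must be >= 0")

    @property
    def sampling_frequency(self) -> float:
        """Nominal rate in Hz: median reciprocal inter-sample interval."""
        return float(1.0 / np.median(np.diff(self.time)))

    @property
    def n_channels(self) -> int:
        return len(self.montage.channels)

    def events(self) -> list:
        """All stimulus events flattened across conditions, onset-ordered."""
        out = [ev for _, evs in self.stims for ev in evs]
        return sorted(out, key=lambda ev: (ev.onset, ev.trial_type))


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _write_str(group: h5py.Group, name: str, value: str) -> None:
    group.create_dataset(name, data=np.bytes_(str(value).encode("utf-8")), dtype=_STR, track_times=False)


def _write_array(group: h5py.Group, name: str, value, dtype=None) -> None:
    group.create_dataset(name, data=np.asarray(value, dtype=dtype), track_times=False)


def write_snirf(rec: SnirfRecording, path) -> None:
    """Write one recording as a single-run SNIRF file."""
    rec.validate()
    montage = rec.montage
    sources = montage.sources()
    detectors = montage.detectors()
    src_index = {o.label: i + 1 for i, o in enumerate(sources)}  # 1-based in-file
    det_index = {o.label: i + 1 for i, o in enumerate(detectors)}
    wavelengths = montage.wavelengths()
    wl_index = {w: i + 1 for i, w in enumerate(wavelengths)}

    with h5py.File(path, "w", track_order=False) as f:
        _write_str(f, "formatVersion", SNIRF_FORMAT_VERSION)
        nirs = f.create_group("nirs", track_order=False)

        meta = nirs.create_group("metaDataTags")
        tags = dict(rec.meta)
        tags.setdefault("LengthUnit", montage.unit)
        tags.setdefault("TimeUnit", "s")
        tags.setdefault("FrequencyUnit", "Hz")
        if montage.coordinate_frame:
            tags.setdefault("nirsbidsCoordinateFrame", montage.coordinate_frame)
        short = sorted(montage.short_pairs())
        if short:
            tags[_SHORT_PAIRS_TAG] = ",".join(f"{s}/{d}" for s, d in short)
        for key in sorted(tags):
            _write_str(meta, key, tags[key])

        data1 = nirs.create_group("data1")
        _write_array(data1, "dataTimeSeries", rec.data, dtype="f8")
        _write_array(data1, "time", rec.time, dtype="f8")
        for k, ch in enumerate(montage.channels, start=1):
            ml = data1.create_group(f"measurementList{k}")
            _write_array(ml, "sourceIndex", src_index[ch.source_label], dtype="i4")
            _write_array(ml, "detectorIndex", det_index[ch.detector_label], dtype="i4")
            _write_array(ml, "wavelengthIndex", wl_index[ch.wavelength_nominal], dtype="i4")
            _write_array(ml, "dataType", CW_AMPLITUDE_DATA_TYPE, dtype="i4")
            _write_array(ml, "dataTypeIndex", 1, dtype="i4")

        probe = nirs.create_group("probe")
        _write_array(probe, "wavelengths", wavelengths, dtype="f8")
        probe.create_dataset(
            "sourceLabels", data=[o.label for o in sources], dtype=_STR, track_times=False
        )
        probe.create_dataset(
            "detectorLabels", data=[o.label for o in detectors], dtype=_STR, track_times=False
        )
        kind = montage.position_kind
        if kind is PositionKind.MEASURED_3D:
            _write_array(probe, "sourcePos3D", [o.position for o in sources], dtype="f8")
            _write_array(probe, "detectorPos3D", [o.position for o in detectors], dtype="f8")
        elif kind is PositionKind.TEMPLATE_2D:
            _write_array(probe, "sourcePos2D", [o.position for o in sources], dtype="f8")
            _write_array(probe, "detectorPos2D", [o.position for o in detectors], dtype="f8")

        for k, (name, events) in enumerate(rec.stims, start=1):
            stim = nirs.create_group(f"stim{k}")
            _write_str(stim, "name", name)
            rows = [
                (ev.onset, ev.duration, float(ev.value) if ev.value is not None else 1.0)
                for ev in sorted(events, key=lambda ev: ev.onset)
            ]
            _write_array(stim, "data", np.asarray(rows, dtype="f8").reshape(-1, 3))

        for k, (name, t, values, unit) in enumerate(rec.aux, start=1):
            aux = nirs.create_group(f"aux{k}")
            _write_str(aux, "name", name)
            _write_array(aux, "time", t, dtype="f8")
            _write_array(aux, "dataTimeSeries", values, dtype="f8")
            if unit:
                _write_str(aux, "dataUnit", unit)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _read_str(ds) -> str:
    value = ds[()]
    if isinstance(value, bytes):
        return value.decode("utf-8")
    if isinstance(value, np.ndarray):  # stored as length-1 array by some writers
        value = value.reshape(-1)[0]
        if isinstance(value, bytes):
            return value.decode("utf-8")
    return str(value)


def _read_scalar_int(group, name, context) -> int:
    if name not in group:
        raise SnirfReadError(f"missing dataset {context}/{name}")
    return int(np.asarray(group[name][()]).reshape(-1)[0])


def _numbered_members(group: h5py.Group, stem: str) -> list:
    """Members named ``<stem><k>`` (or bare ``<stem>``), sorted by k."""
    pat = re.compile(rf"^{stem}(\d*)$")
    found = []
    for key in group:
        m = pat.match(key)
        if m:
            found.append((int(m.group(1) or "1"), key))
    return [key for _, key in sorted(found)]


def read_snirf(path) -> SnirfRecording:
    """Read a single-run CW SNIRF file into a :class:`SnirfRecording`.

    Raises a structured error naming the absent group for malformed files,
    :class:`SnirfMultipleRunsError` for files carrying more than one run,
    :class:`SnirfUnsupportedError` for non-CW payloads, and
    :class:`SnirfIntegrityError` for dangling probe indices.
    """
    path = Path(path)
    if not path.exists():
        raise SnirfReadError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        nirs_groups = _numbered_members(f, "nirs")
        if not nirs_groups:
            raise SnirfReadError("missing required group /nirs")
        if len(nirs_groups) > 1:
            raise SnirfMultipleRunsError(
                f"file holds {len(nirs_groups)} nirs groups; BIDS-compliant SNIRF "
                "files must contain data from a single run only"
            )
        nirs = f[nirs_groups[0]]

        data_groups = _numbered_members(nirs, "data")
        if not data_groups:
            raise SnirfReadError("missing required group /nirs/data1")
        if len(data_groups) > 1:
            raise SnirfMultipleRunsError(
                f"file holds {len(data_groups)} data blocks; BIDS-compliant SNIRF "
                "files must contain data from a single run only"
            )
        data1 = nirs[data_groups[0]]
        for req in ("dataTimeSeries", "time"):
            if req not in data1:
                raise SnirfReadError(f"missing required dataset /nirs/data1/{req}")
        data = np.asarray(data1["dataTimeSeries"][()], dtype=float)
        time = np.asarray(data1["time"][()], dtype=float).reshape(-1)
        if data.ndim == 1:
            data = data.reshape(-1, 1)

        if "probe" not in nirs:
            raise SnirfReadError("missing required group /nirs/probe")
        probe = nirs["probe"]
        if "wavelengths" not in probe:
            raise SnirfReadError("missing required dataset /nirs/probe/wavelengths")
        wavelengths = np.asarray(probe["wavelengths"][()], dtype=float).reshape(-1)

        def labels(name, n, prefix):
            if name in probe:
                return [
                    v.decode("utf-8") if isinstance(v, bytes) else str(v)
                    for v in np.asarray(probe[name][()]).reshape(-1)
                ]
            return [f"{prefix}{i + 1}" for i in range(n)]

        def positions(name3d, name2d):
            if name3d in probe:
                return np.asarray(probe[name3d][()], dtype=float), PositionKind.MEASURED_3D
            if name2d in probe:
                return np.asarray(probe[name2d][()], dtype=float), PositionKind.TEMPLATE_2D
            return None, PositionKind.ABSENT

        src_pos, src_kind = positions("sourcePos3D", "sourcePos2D")
        det_pos, det_kind = positions("detectorPos3D", "detectorPos2D")
        if (src_pos is None) != (det_pos is None) or (
            src_pos is not None and src_kind is not det_kind
        ):
            raise SnirfReadError("source and detector position kinds disagree in /nirs/probe")

        n_sources = len(src_pos) if src_pos is not None else 0
        n_detectors = len(det_pos) if det_pos is not None else 0
        src_labels = labels("sourceLabels", n_sources, "S")
        det_labels = labels("detectorLabels", n_detectors, "D")
        n_sources = max(n_sources, len(src_labels))
        n_detectors = max(n_detectors, len(det_labels))

        meta: dict = {}
        if "metaDataTags" in nirs:
            for key, ds in nirs["metaDataTags"].items():
                meta[key] = _read_str(ds)
        short_pairs = set()
        tag = meta.pop(_SHORT_PAIRS_TAG, None)
        if tag:
            short_pairs = {tuple(item.split("/", 1)) for item in tag.split(",") if item}

        fs = float(1.0 / np.median(np.diff(time))) if time.size > 1 else 1.0

        ml_groups = _numbered_members(data1, "measurementList")
        if not ml_groups:
            raise SnirfReadError("missing /nirs/data1/measurementList entries")
        if data.shape[1] != len(ml_groups):
            raise SnirfIntegrityError(
                f"dataTimeSeries has {data.shape[1]} columns but "
                f"{len(ml_groups)} measurementList entries"
            )
        channels = []
        used_src, used_det = set(), set()
        for key in ml_groups:
            ml = data1[key]
            ctx = f"/nirs/data1/{key}"
            dtype_code = _read_scalar_int(ml, "dataType", ctx)
            if dtype_code != CW_AMPLITUDE_DATA_TYPE:
                raise SnirfUnsupportedError(
                    f"{ctx}: dataType {dtype_code} is not continuous-wave amplitude; "
                    "time-domain/frequency-domain payloads are not yet supported"
                )
            si = _read_scalar_int(ml, "sourceIndex", ctx)
            di = _read_scalar_int(ml, "detectorIndex", ctx)
            wi = _read_scalar_int(ml, "wavelengthIndex", ctx)
            if not (1 <= si <= n_sources):
                raise SnirfIntegrityError(f"{ctx}: sourceIndex {si} beyond {n_sources} sources")
            if not (1 <= di <= n_detectors):
                raise SnirfIntegrityError(f"{ctx}: detectorIndex {di} beyond {n_detectors} detectors")
            if not (1 <= wi <= wavelengths.size):
                raise SnirfIntegrityError(
                    f"{ctx}: wavelengthIndex {wi} beyond {wavelengths.size} wavelengths"
                )
            src, det, wl = src_labels[si - 1], det_labels[di - 1], float(wavelengths[wi - 1])
            used_src.add(si - 1)
            used_det.add(di - 1)
            channels.append(
                ChannelDef(
                    name=default_channel_name(src, det, wl),
                    source_label=src,
                    detector_label=det,
                    wavelength_nominal=wl,
                    sampling_frequency=fs,
                    short_channel=(src, det) in short_pairs,
                )
            )

        optodes = []
        for i, label in enumerate(src_labels):
            pos = tuple(src_pos[i]) if src_pos is not None else None
            optodes.append(OptodeDef(label=label, role=OptodeRole.SOURCE, position=pos))
        for i, label in enumerate(det_labels):
            pos = tuple(det_pos[i]) if det_pos is not None else None
            optodes.append(OptodeDef(label=label, role=OptodeRole.DETECTOR, position=pos))

        # canonical tags the writer injects become structured fields again,
        # so write -> read is the identity on the data model
        unit = meta.pop("LengthUnit", "mm")
        frame = meta.pop("nirsbidsCoordinateFrame", None)
        if meta.get("TimeUnit") == "s":
            meta.pop("TimeUnit")
        if meta.get("FrequencyUnit") == "Hz":
            meta.pop("FrequencyUnit")
        montage = Montage(optodes=optodes, channels=channels, coordinate_frame=frame, unit=unit)

        stims = []
        for key in _numbered_members(nirs, "stim"):
            stim = nirs[key]
            name = _read_str(stim["name"]) if "name" in stim else key
            rows = np.asarray(stim["data"][()], dtype=float).reshape(-1, 3) if "data" in stim else np.empty((0, 3))
            events = [
                EventRecord(onset=float(o), duration=float(d), trial_type=name, value=float(v))
                for o, d, v in rows
            ]
            stims.append((name, events))

        aux = []
        for key in _numbered_members(nirs, "aux"):
            grp = nirs[key]
            name = _read_str(grp["name"]) if "name" in grp else key
            t = np.asarray(grp["time"][()], dtype=float).reshape(-1) if "time" in grp else np.array([])
            values = (
                np.asarray(grp["dataTimeSeries"][()], dtype=float).reshape(-1)
                if "dataTimeSeries" in grp
                else np.array([])
            )
            unit_str = _read_str(grp["dataUnit"]) if "dataUnit" in grp else ""
            aux.append((name, t, values, unit_str))

    rec = SnirfRecording(time=time, data=data, montage=montage, stims=stims, aux=aux, meta=meta)
    rec.validate()
    return rec


def extract_sidecar_seed(rec: SnirfRecording) -> SidecarSet:
    """Draft sidecars filled with everything duplicatable from the SNIRF content.

    Study-level fields (``TaskName`` etc.) are left empty for the converter.
    """
    montage = rec.montage
    channels = channels_table_from_montage(montage)
    nirs_json = {
        "TaskName": "",
        "SamplingFrequency": rec.sampling_frequency,
        "NIRSChannelCount": rec.n_channels,
        "NIRSSourceOptodeCount": len(montage.sources()),
        "NIRSDetectorOptodeCount": len(montage.detectors()),
        "ShortChannelCounts": short_pair_count(channels),
    }
    events = rec.events()
    return SidecarSet(
        nirs_json=nirs_json,
        channels_table=channels,
        optodes_table=optodes_table_from_montage(montage),
        coordsystem=coordsystem_from_montage(montage),
        events_table=events_table_from_records(events) if events else None,
    )
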