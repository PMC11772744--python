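"""Core domain types for continuous-wave fNIRS data organization.

Terminology follows the NIRS-BIDS convention: a *source* is a light
emitting device, a *detector* is a photoelectric transducer, and *optode*
is the umbrella term for either.  A *channel* is one optical signal at a
single nominal wavelength for one source-detector pair, so a pair measured
at W wavelengths contributes W channels.

This module also owns the BIDS entity/filename grammar
(``sub-<label>[_ses-<label>][_run-<index>]_task-<label>_<suffix>.<ext>``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Union

#: Literal text used for missing values in tabular sidecar files, including
#: the z coordinate of flattened 2-D template optode layouts.
NA = "n/a"


class NirsBidsError(ValueError):
    """Base class for domain errors raised by this package."""


class BidsNameError(NirsBidsError):
    """A BIDS basename could not be formatted or parsed."""


class OptodeRole(str, Enum):
    SOURCE = "source"
    DETECTOR = "detector"


class ChannelType(str, Enum):
    """Channel kinds carried in the channels table.

    Only continuous-wave amplitude channels hold optical data here; the
    remaining members are reserved for auxiliary sensor kinds.
    """

    NIRSCWAMPLITUDE = "NIRSCWAMPLITUDE"
    ACCEL = "ACCEL"
    GYRO = "GYRO"
    MISC = "MISC"


class PositionKind(str, Enum):
    MEASURED_3D = "measured3d"
    TEMPLATE_2D = "template2d"
    ABSENT = "absent"


class Severity(str, Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


@dataclass(frozen=True)
class OptodeDef:
    """One optode: label, role, and optionally a position.

    ``position`` is either a 3-tuple (measured or template 3-D coordinates),
    a 2-tuple (flattened 2-D template layout whose third coordinate is the
    missing marker, never a number), or ``None`` (no digitization at all).
    """

    label: str
    role: OptodeRole
    position: Optional[tuple] = None

    def __post_init__(self) -> None:
        if not self.label:
            raise NirsBidsError("optode label must be non-empty")
        if not isinstance(self.role, OptodeRole):
            object.__setattr__(self, "role", OptodeRole(self.role))
        if self.position is not None:
            pos = tuple(float(v) for v in self.position)
            if len(pos) not in (2, 3):
                raise NirsBidsError(
                    f"optode {self.label!r}: position must have 2 or 3 "
                    f"coordinates, got {len(pos)}"
                )
            object.__setattr__(self, "position", pos)

    @property
    def position_kind(self) -> PositionKind:
        if self.position is None:
            return PositionKind.ABSENT
        return PositionKind.TEMPLATE_2D if len(self.position) == 2 else PositionKind.MEASURED_3D


@dataclass(frozen=True)
class ChannelDef:
    """One optical signal: a source-detector pair at a single wavelength."""

    name: str
    source_label: str
    detector_label: str
    wavelength_nominal: float  # nm
    sampling_frequency: float  # Hz
    short_channel: bool = False
    channel_type: ChannelType = ChannelType.NIRSCWAMPLITUDE

    def __post_init__(self) -> None:
        if not self.name:
            raise NirsBidsError("channel name must be non-empty")
        if self.wavelength_nominal <= 0:
            raise NirsBidsError(f"channel {self.name!r}: wavelength must be positive")
        if self.sampling_frequency <= 0:
            raise NirsBidsError(f"channel {self.name!r}: sampling frequency must be positive")
        if not isinstance(self.channel_type, ChannelType):
            object.__setattr__(self, "channel_type", ChannelType(self.channel_type))

    @property
    def pair(self) -> tuple:
        return (self.source_label, self.detector_label)


@dataclass
class Montage:
    """Probe geometry plus the per-wavelength channel table."""

    optodes: list = field(default_factory=list)
    channels: list = field(default_factory=list)
    coordinate_frame: Optional[str] = None  # e.g. "MNI152NLin2009cAsym" or "custom"
    unit: str = "mm"

    def validate(self) -> None:
        labels = [o.label for o in self.optodes]
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise NirsBidsError(f"duplicate optode labels in montage: {dup}")
        sources = {o.label for o in self.optodes if o.role is OptodeRole.SOURCE}
        detectors = {o.label for o in self.optodes if o.role is OptodeRole.DETECTOR}
        for ch in self.channels:
            if ch.source_label not in sources:
                raise NirsBidsError(
                    f"channel {ch.name!r}: source {ch.source_label!r} is not a "
                    "source optode of this montage"
                )
            if ch.detector_label not in detectors:
                raise NirsBidsError(
                    f"channel {ch.name!r}: detector {ch.detector_label!r} is not a "
                    "detector optode of this montage"
                )
        kinds = {o.position_kind for o in self.optodes}
        if len(kinds) > 1:
            raise NirsBidsError(
                f"all optode positions must share one kind, found {sorted(k.value for k in kinds)}"
            )
        # short flag must agree across wavelengths of one pair
        by_pair: dict = {}
        for ch in self.channels:
            prev = by_pair.setdefault(ch.pair, ch.short_channel)
            if prev != ch.short_channel:
                raise NirsBidsError(
                    f"pair {ch.pair}: short_channel flag differs between wavelengths"
                )

    @property
    def position_kind(self) -> PositionKind:
        kinds = {o.position_kind for o in self.optodes}
        if not kinds:
            return PositionKind.ABSENT
        if len(kinds) > 1:
            raise NirsBidsError("mixed optode position kinds")
        return kinds.pop()

    def sources(self) -> list:
        return [o for o in self.optodes if o.role is OptodeRole.SOURCE]

    def detectors(self) -> list:
        return [o for o in self.optodes if o.role is OptodeRole.DETECTOR]

    def short_pairs(self) -> set:
        return {ch.pair for ch in self.channels if ch.short_channel}

    def wavelengths(self) -> list:
        """Distinct nominal wavelengths, sorted ascending."""
        return sorted({ch.wavelength_nominal for ch in self.channels})


@dataclass(frozen=True)
class EventRecord:
    """One experimental event: onset/duration in seconds from recording start."""

    onset: float
    duration: float
    trial_type: str
    value: Optional[Union[float, str]] = None
    response: Optional[str] = None

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise NirsBidsError(f"event onset must be >= 0, got {self.onset}")
        if self.duration < 0:
            raise NirsBidsError(f"event duration must be >= 0, got {self.duration}")


@dataclass(frozen=True)
class ValidationIssue:
    """One validator finding, tied to a rule code from the rule catalogue."""

    code: str
    severity: Severity
    path: str  # relative to dataset root
    message: str

    def as_dict(self) -> dict:
        return {
            "code": self.code,
            "severity": self.severity.value,
            "path": self.path,
            "message": self.message,
        }


# ---------------------------------------------------------------------------
# BIDS entities and the filename grammar
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"^[a-zA-Z0-9]+$")

#: Known suffixes and their default file extensions.
SUFFIX_EXTENSIONS = {
    "nirs": ".snirf",
    "channels": ".tsv",
    "optodes": ".tsv",
    "coordsystem": ".json",
    "events": ".tsv",
}

_KNOWN_EXTENSIONS = (".snirf", ".json", ".tsv")


@dataclass(frozen=True)
class BidsEntities:
    """The entity tuple of one run: subject, optional session, task, optional run.

    Labels are stored without their ``sub-``/``ses-``/... prefixes; prefixes
    are a rendering concern of the filename grammar.
    """

    subject: str
    task: str
    session: Optional[str] = None
    run: Optional[int] = None

    def __post_init__(self) -> None:
        for key, value in (("subject", self.subject), ("session", self.session), ("task", self.task)):
            if value is None:
                continue
            if not _LABEL_RE.match(value):
                raise BidsNameError(
                    f"{key} label {value!r} must be alphanumeric "
                    "(no '_', '-', '/', '.' or spaces)"
                )
        if self.run is not None:
            run = int(self.run)
            if run < 1:
                raise BidsNameError(f"run index must be >= 1, got {run}")
            object.__setattr__(self, "run", run)


def format_bids_basename(entities: BidsEntities, suffix: str, extension: Optional[str] = None) -> str:
    """Render the canonical BIDS basename for one run's file.

    Entities appear in the fixed order subject, session, run, task; absent
    entities are omitted entirely.  ``extension`` overrides the default for
    the suffix (e.g. ``.json`` for the ``_nirs.json`` sidecar).

    >>> format_bids_basename(BidsEntities(subject="01", task="tapping"), "nirs")
    'sub-01_task-tapping_nirs.snirf'
    """
    if suffix not in SUFFIX_EXTENSIONS:
        raise BidsNameError(
            f"unknown suffix {suffix!r}; expected one of {sorted(SUFFIX_EXTENSIONS)}"
        )
    ext = SUFFIX_EXTENSIONS[suffix] if extension is None else extension
    parts = [f"sub-{entities.subject}"]
    if entities.session is not None:
        parts.append(f"ses-{entities.session}")
    if entities.run is not None:
        parts.append(f"run-{entities.run}")
    parts.append(f"task-{entities.task}")
    parts.append(suffix)
    return "_".join(parts) + ext


def parse_bids_basename(name: str):
    """Parse a BIDS basename back into ``(BidsEntities, suffix)``.

    Exact inverse of :func:`format_bids_basename` on its image.  The parser
    additionally tolerates task-before-run ordering and canonicalizes it;
    any other deviation (unknown entity key, duplicate entity, wrong order,
    unknown suffix or extension) is a :class:`BidsNameError` naming the
    offending token.
    """
    for ext in _KNOWN_EXTENSIONS:
        if name.endswith(ext):
            stem = name[: -len(ext)]
            break
    else:
        raise BidsNameError(f"unknown file extension on {name!r}")

    tokens = stem.split("_")
    if len(tokens) < 2:
        raise BidsNameError(f"basename {name!r} has no suffix token")
    suffix = tokens[-1]
    if suffix not in SUFFIX_EXTENSIONS:
        raise BidsNameError(f"unknown suffix {suffix!r} in {name!r}")

    entities: dict = {}
    order: list = []
    for token in tokens[:-1]:
        if "-" not in token:
            raise BidsNameError(f"malformed entity token {token!r} in {name!r}")
        key, _, value = token.partition("-")
        if key not in ("sub", "ses", "run", "task"):
            raise BidsNameError(f"unrecognized entity key {key!r} in {name!r}")
        if key in entities:
            raise BidsNameError(f"duplicate entity {key!r} in {name!r}")
        if not value:
            raise BidsNameError(f"empty value for entity {key!r} in {name!r}")
        entities[key] = value
        order.append(key)

    if "sub" not in entities:
        raise BidsNameError(f"missing required entity 'sub' in {name!r}")
    if "task" not in entities:
        raise BidsNameError(f"missing required entity 'task' in {name!r}")

    # canonical order is sub, ses, run, task; tolerate run/task swapped
    canonical = [k for k in ("sub", "ses", "run", "task") if k in entities]
    swapped = [k for k in ("sub", "ses", "task", "run") if k in entities]
    if order != canonical and order != swapped:
        raise BidsNameError(
            f"entities out of order in {name!r}: got {order}, expected {canonical}"
        )

    run = entities.get("run")
    if run is not None:
        if not run.isdigit():
            raise BidsNameError(f"run index {run!r} in {name!r} is not an integer")
        run = int(run)
    ent = BidsEntities(
        subject=entities["sub"],
        task=entities["task"],
        session=entities.get("ses"),
        run=run,
    )
    return ent, suffix


def default_channel_name(source_label: str, detector_label: str, wavelength: float) -> str:
    """The package's channel naming convention: ``"S1_D2 760nm"``."""
    return f"{source_label}_{detector_label} {wavelength:g}nm"


def expand_pairs_to_channels(
    pairs: Sequence,
    wavelengths: Sequence,
    fs: float,
    name_fn=default_channel_name,
) -> list:
    """Expand ``(source, detector, short?)`` pairs into per-wavelength channels.

    Each source-detector pair measured at W wavelengths yields W channels,
    with the short-channel flag propagated to every wavelength of the pair.
    """
    if not wavelengths:
        raise NirsBidsError("wavelength list must be non-empty")
    if any(w <= 0 for w in wavelengths):
        raise NirsBidsError("all wavelengths must be positive")
    channels = []
    for src, det, short in pairs:
        for wl in wavelengths:
            channels.append(
                ChannelDef(
                    name=name_fn(src, det, wl),
                    source_label=src,
                    detector_label=det,
                    wavelength_nominal=float(wl),
                    sampling_frequency=float(fs),
                    short_channel=bool(short),
                )
            )
    return channels
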