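"""Synthetic continuous-wave fNIRS studies: montages, signals, events.

The generator fabricates complete, validator-clean studies so that every
other part of the toolkit is testable without downloading data.  It also
ships parameterized replicas of four published example datasets (finger/leg
movements, motor task, passive auditory, audio-visual speech); their printed
structural parameters — participant counts, source/detector counts,
short-channel counts, condition counts — are honored exactly, while
quantities the descriptions do not print (long-channel pair lists, block
timing, sampling rates) are package conventions documented in the methods
note.

Signal model per channel: strictly positive intensity

    I(t) = B * (1 + a_c sin(2*pi*f_c t + phi) + a_m sin(2*pi*0.3 t + phi')
               + s * a_task * boxcar(t) + eps(t))

with a cardiac oscillation near 1 Hz, a Mayer-wave oscillation near 0.3 Hz,
a task-locked boxcar in long channels only (intensity falls at the longer
wavelength and rises at the shorter one, mimicking an oxygenation response;
1-2 % of baseline), and bounded uniform noise.  All modulation amplitudes
sum to < 10 % of baseline, so amplitudes stay positive for every seed.
Short-separation pairs receive the physiological components but no task
component, as they predominantly sample extracerebral tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .convert import DatasetSummary, StudyDescription, build_dataset
from .model import (
    BidsEntities,
    EventRecord,
    Montage,
    NirsBidsError,
    OptodeDef,
    OptodeRole,
    expand_pairs_to_channels,
)
from .snirf import SnirfRecording

LONG_SEPARATION_MM = 30.0  # typical adult source-detector separation
SHORT_SEPARATION_MM = 8.0  # typical short-channel separation

# modulation amplitudes, as fractions of baseline
_CARDIAC_AMP = 0.02
_MAYER_AMP = 0.015
_TASK_AMP = 0.015
_NOISE_AMP = 0.01


@dataclass(frozen=True)
class MontageSpec:
    """Probe layout parameters: optode counts, pair counts, wavelengths."""

    n_sources: int
    n_detectors: int  # regular (long-channel) detectors, excluding short ones
    long_pairs: int
    short_pairs: int
    wavelengths: tuple = (760.0, 850.0)
    coordinate_kind: str = "measured3d"  # or "template2d"

    def validate(self) -> None:
        if self.n_sources < 1 or self.n_detectors < 0 or self.short_pairs < 0:
            raise NirsBidsError("optode counts must be non-negative (>=1 source)")
        if self.long_pairs + self.short_pairs < 1:
            raise NirsBidsError("montage must define at least one source-detector pair")
        if self.long_pairs > 0 and self.n_detectors < 1:
            raise NirsBidsError("long pairs require at least one regular detector")
        if len(self.wavelengths) < 2:
            raise NirsBidsError("CW spectroscopy needs two or more wavelengths")
        if any(w <= 0 for w in self.wavelengths):
            raise NirsBidsError("wavelengths must be positive")
        if self.coordinate_kind not in ("measured3d", "template2d", "absent"):
            raise NirsBidsError(f"unknown coordinate kind {self.coordinate_kind!r}")


@dataclass(frozen=True)
class TaskSpec:
    """Block-design task: named conditions presented in round-robin blocks."""

    name: str
    conditions: tuple
    block_duration_s: float = 5.0
    inter_block_interval_s: float = 15.0
    n_blocks_per_condition: int = 2

    def validate(self) -> None:
        if not self.conditions:
            raise NirsBidsError("task must define at least one condition")
        if self.block_duration_s <= 0 or self.inter_block_interval_s < 0:
            raise NirsBidsError("block duration must be positive, interval non-negative")
        if self.n_blocks_per_condition < 1:
            raise NirsBidsError("need at least one block per condition")

    @property
    def required_duration_s(self) -> float:
        cycle = self.block_duration_s + self.inter_block_interval_s
        return self.inter_block_interval_s + (
            self.n_blocks_per_condition * len(self.conditions) * cycle
        )


@dataclass(frozen=True)
class StudySpec:
    """Everything needed to fabricate one synthetic study deterministically."""

    name: str
    n_participants: int
    montage_spec: MontageSpec
    task_spec: TaskSpec
    fs: float = 10.0
    duration_s: Optional[float] = None  # default: task requirement + 10 s tail
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise NirsBidsError("study needs at least one participant")
        if self.fs <= 0:
            raise NirsBidsError("sampling frequency must be positive")
        self.montage_spec.validate()
        self.task_spec.validate()
        if self.duration_s is not None and self.duration_s < self.task_spec.required_duration_s:
            raise NirsBidsError(
                f"duration {self.duration_s} s is too short for the requested blocks "
                f"(need >= {self.task_spec.required_duration_s} s)"
            )

    @property
    def effective_duration_s(self) -> float:
        if self.duration_s is not None:
            return self.duration_s
        return self.task_spec.required_duration_s + 10.0


# ---------------------------------------------------------------------------
# montage construction
# ---------------------------------------------------------------------------


def _grid_positions(mspec: MontageSpec):
    """Checkerboard layout with 30 mm pitch: adjacent cells alternate roles,
    so nearest source-detector separations are exactly the long separation."""
    n_cells = 2 * max(mspec.n_sources, mspec.n_detectors)
    side = max(2, math.ceil(math.sqrt(n_cells)) + 1)
    src_cells, det_cells = [], []
    for j in range(side):
        for i in range(side):
            (src_cells if (i + j) % 2 == 0 else det_cells).append((i, j))
    if len(src_cells) < mspec.n_sources or len(det_cells) < mspec.n_detectors:
        side += 2  # pathological aspect ratios; enlarge once
        src_cells, det_cells = [], []
        for j in range(side):
            for i in range(side):
                (src_cells if (i + j) % 2 == 0 else det_cells).append((i, j))
    center = (side - 1) / 2.0
    to_xy = lambda c: (  # noqa: E731
        LONG_SEPARATION_MM * (c[0] - center),
        LONG_SEPARATION_MM * (c[1] - center),
    )
    src_xy = [to_xy(c) for c in src_cells[: mspec.n_sources]]
    det_xy = [to_xy(c) for c in det_cells[: mspec.n_detectors]]
    return src_xy, det_xy


def _project_scalp(xy, radius: float):
    """Lift a flat layout onto a sphere of the given radius (scalp patch)."""
    x, y = xy
    z2 = radius * radius - x * x - y * y
    return (x, y, math.sqrt(max(z2, 0.0)))


def _long_pairing(src_xy, det_xy, n_pairs: int):
    """Deterministic nearest-neighbour pairing that first covers every
    detector, then every source, then fills with the closest remaining pairs."""

    def dist(si, di):
        dx = src_xy[si][0] - det_xy[di][0]
        dy = src_xy[si][1] - det_xy[di][1]
        return math.hypot(dx, dy)

    chosen, seen = [], set()

    def add(si, di):
        if (si, di) not in seen:
            seen.add((si, di))
            chosen.append((si, di))

    for di in range(len(det_xy)):
        si = min(range(len(src_xy)), key=lambda s: (dist(s, di), s))
        add(si, di)
    for si in range(len(src_xy)):
        if si not in {p[0] for p in chosen}:
            di = min(range(len(det_xy)), key=lambda d: (dist(si, d), d))
            add(si, di)
    remaining = sorted(
        ((si, di) for si in range(len(src_xy)) for di in range(len(det_xy)) if (si, di) not in seen),
        key=lambda p: (dist(*p), p),
    )
    for si, di in remaining:
        if len(chosen) >= n_pairs:
            break
        add(si, di)
    return chosen[:n_pairs]


def build_montage(mspec: MontageSpec, fs: float) -> Montage:
    """Construct the probe geometry and per-wavelength channel table.

    Long pairs sit at ~30 mm separation on a scalp patch; each short pair
    adds a dedicated detector 8 mm from its source (sources are reused in
    round-robin when there are more short pairs than sources).
    """
    mspec.validate()
    src_xy, det_xy = _grid_positions(mspec)

    short_xy = []
    short_src = []
    for k in range(mspec.short_pairs):
        si = k % mspec.n_sources
        x, y = src_xy[si]
        short_xy.append((x + SHORT_SEPARATION_MM, y))
        short_src.append(si)

    all_xy = src_xy + det_xy + short_xy
    radius = max(math.hypot(x, y) for x, y in all_xy) + 20.0 if all_xy else 87.0

    def position(xy):
        if mspec.coordinate_kind == "absent":
            return None
        if mspec.coordinate_kind == "template2d":
            return xy
        return _project_scalp(xy, radius)

    optodes = [
        OptodeDef(label=f"S{i + 1}", role=OptodeRole.SOURCE, position=position(xy))
        for i, xy in enumerate(src_xy)
    ]
    optodes += [
        OptodeDef(label=f"D{i + 1}", role=OptodeRole.DETECTOR, position=position(xy))
        for i, xy in enumerate(det_xy)
    ]
    optodes += [
        OptodeDef(
            label=f"D{mspec.n_detectors + k + 1}",
            role=OptodeRole.DETECTOR,
            position=position(xy),
        )
        for k, xy in enumerate(short_xy)
    ]

    pairs = [
        (f"S{si + 1}", f"D{di + 1}", False)
        for si, di in _long_pairing(src_xy, det_xy, mspec.long_pairs)
    ]
    pairs += [
        (f"S{si + 1}", f"D{mspec.n_detectors + k + 1}", True)
        for k, si in enumerate(short_src)
    ]

    channels = expand_pairs_to_channels(pairs, mspec.wavelengths, fs)
    frame = None if mspec.coordinate_kind == "absent" else "custom"
    montage = Montage(optodes=optodes, channels=channels, coordinate_frame=frame, unit="mm")
    montage.validate()
    return montage


# ---------------------------------------------------------------------------
# signal and study generation
# ---------------------------------------------------------------------------


def _block_events(task: TaskSpec) -> list:
    events = []
    cycle = task.block_duration_s + task.inter_block_interval_s
    onset = task.inter_block_interval_s
    for _ in range(task.n_blocks_per_condition):
        for condition in task.conditions:
            events.append(
                EventRecord(onset=onset, duration=task.block_duration_s, trial_type=condition, value=1.0)
            )
            onset += cycle
    return events


def generate_recording(spec: StudySpec, participant_index: int) -> SnirfRecording:
    """Fabricate one participant's run; fully reproducible from the study seed."""
    spec.validate()
    if participant_index < 0 or participant_index >= spec.n_participants:
        raise NirsBidsError(
            f"participant index {participant_index} outside 0..{spec.n_participants - 1}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), participant_index]))
    montage = build_montage(spec.montage_spec, spec.fs)

    duration = spec.effective_duration_s
    if duration < spec.task_spec.required_duration_s:
        raise NirsBidsError("duration too short to fit the requested blocks")
    n_times = int(round(duration * spec.fs))
    t = np.arange(n_times) / spec.fs

    events = _block_events(spec.task_spec)
    boxcars = {}
    for condition in spec.task_spec.conditions:
        box = np.zeros(n_times)
        for ev in events:
            if ev.trial_type == condition:
                box[(t >= ev.onset) & (t < ev.onset + ev.duration)] = 1.0
        boxcars[condition] = box
    task_wave = sum(boxcars.values())  # blocks never overlap in the round-robin layout

    longest_wl = max(spec.montage_spec.wavelengths)
    f_cardiac = rng.uniform(0.9, 1.1)
    data = np.empty((n_times, len(montage.channels)))
    for c, ch in enumerate(montage.channels):
        baseline = rng.uniform(0.5, 1.5)
        phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
        signal = (
            1.0
            + _CARDIAC_AMP * np.sin(2 * np.pi * f_cardiac * t + phase1)
            + _MAYER_AMP * np.sin(2 * np.pi * 0.3 * t + phase2)
            + rng.uniform(-_NOISE_AMP, _NOISE_AMP, size=n_times)
        )
        if not ch.short_channel:
            sign = -1.0 if ch.wavelength_nominal == longest_wl else 1.0
            signal = signal + sign * _TASK_AMP * task_wave
        data[:, c] = baseline * signal

    stims = [
        (condition, [ev for ev in events if ev.trial_type == condition])
        for condition in spec.task_spec.conditions
    ]
    meta = {
        "SubjectID": f"{participant_index + 1:02d}",
        "MeasurementDate": "2023-06-15",
        "MeasurementTime": "09:00:00",
    }
    rec = SnirfRecording(time=t, data=data, montage=montage, stims=stims, meta=meta)
    rec.validate()
    return rec


#: Replica parameter sets for the four published example datasets.  Printed
#: parameters (participants, optode counts, short pairs, conditions) are
#: exact; unprinted ones (long-pair counts, timing, rates) are conventions.
_REPLICAS = {
    "automatic_movements": StudySpec(
        name="Automatic and non-automatic finger and leg movements (synthetic replica)",
        n_participants=24,
        montage_spec=MontageSpec(
            n_sources=8, n_detectors=8, long_pairs=24, short_pairs=12,
            coordinate_kind="template2d",
        ),
        task_spec=TaskSpec(
            name="movements",
            conditions=("fingerauto", "fingernonauto", "footauto", "footnonauto"),
            block_duration_s=20.0,
            inter_block_interval_s=10.0,
            n_blocks_per_condition=2,
        ),
        fs=10.0,
    ),
    "motor_task": StudySpec(
        name="Motor task (synthetic replica)",
        n_participants=5,
        montage_spec=MontageSpec(n_sources=8, n_detectors=8, long_pairs=20, short_pairs=8),
        task_spec=TaskSpec(
            name="tapping",
            conditions=("tappingleft", "tappingright", "control"),
            block_duration_s=5.0,
            inter_block_interval_s=15.0,
            n_blocks_per_condition=3,
        ),
        fs=7.8,
    ),
    "passive_auditory": StudySpec(
        name="Passive auditory task (synthetic replica)",
        n_participants=17,
        montage_spec=MontageSpec(n_sources=16, n_detectors=16, long_pairs=40, short_pairs=8),
        task_spec=TaskSpec(
            name="auditory",
            conditions=("speech", "noise", "silence"),
            block_duration_s=5.0,
            inter_block_interval_s=15.0,
            n_blocks_per_condition=2,
        ),
        fs=10.0,
    ),
    "audio_visual": StudySpec(
        name="Active visual and auditory tasks (synthetic replica)",
        n_participants=17,
        montage_spec=MontageSpec(n_sources=16, n_detectors=16, long_pairs=40, short_pairs=8),
        task_spec=TaskSpec(
            name="audiovisual",
            conditions=("audiospeech", "visualspeech", "control"),
            block_duration_s=5.0,
            inter_block_interval_s=10.0,
            n_blocks_per_condition=2,
        ),
        fs=10.0,
    ),
}

REPLICA_NAMES = tuple(sorted(_REPLICAS))


def replica_spec(name: str, seed: int = 0) -> StudySpec:
    """The StudySpec encoding the printed parameters of a named example dataset."""
    if name not in _REPLICAS:
        raise NirsBidsError(
            f"unknown example dataset {name!r}; valid names: {', '.join(REPLICA_NAMES)}"
        )
    return replace(_REPLICAS[name], seed=int(seed))


def _participants_roster(spec: StudySpec) -> list:
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 9999]))
    rows = []
    for i in range(spec.n_participants):
        rows.append(
            {
                "participant_id": f"sub-{i + 1:02d}",
                "age": int(rng.integers(20, 60)),
                "sex": "M" if i % 2 == 0 else "F",
            }
        )
    return rows


def generate_study(spec: StudySpec, root) -> DatasetSummary:
    """Fabricate a complete NIRS-BIDS tree at ``root`` (validator-clean)."""
    spec.validate()
    from . import __version__

    study = StudyDescription(
        name=spec.name,
        authors=["nirsbids synthetic data generator"],
        participants=_participants_roster(spec),
        generated_by=[
            {
                "Name": "nirsbids.synth",
                "Version": __version__,
                "Description": f"synthetic study generated with seed={spec.seed}",
            }
        ],
    )
    runs = []
    for i in range(spec.n_participants):
        rec = generate_recording(spec, i)
        runs.append((rec, BidsEntities(subject=f"{i + 1:02d}", task=spec.task_spec.name)))
    return build_dataset(runs, study, root)
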