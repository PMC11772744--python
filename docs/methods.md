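# Methods

This note records the conventions, numerical choices and open design
decisions behind `nirsbids`, in the spirit of a package methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The data model

A **run** is one `SnirfRecording`: a strictly increasing time vector in
seconds, a samples x channels matrix of non-negative finite CW intensities,
a `Montage`, per-condition stimulus blocks, auxiliary series from the same
device, and free-form metadata tags. One SNIRF file carries exactly one run;
this is enforced symmetrically (the writer cannot emit a second data block,
the reader refuses files containing one, and the validator flags such files
with `NB206`).

A **montage** couples optodes (label + role `source`/`detector` + optional
position) to per-wavelength channels. Channel identity is
(source, detector, wavelength): a pair measured at W wavelengths is W
channels, named `"S1_D2 760nm"` by convention — any unique non-empty name
validates. The short-channel flag is a property of the *pair* and must agree
across its wavelengths.

Optode positions come in exactly one kind per montage:

- **measured 3-D** — digitized (x, y, z) in a declared unit and frame;
- **template 2-D** — flattened layout; only x and y exist, and the third
  coordinate is rendered as the literal `n/a` in `_optodes.tsv` (never a
  number — the validator warns with `NB302` when it finds numeric z on a
  2-D layout);
- **absent** — no positions; no optodes/coordsystem files are emitted.

## Filename grammar

Entities render in the fixed order `sub-`, `ses-`, `run-`, `task-` followed
by the suffix (`nirs`, `channels`, `optodes`, `coordsystem`, `events`).
Labels are strictly alphanumeric; absent entities leave no trace in the
name. The parser is the exact inverse on the grammar's image and
additionally accepts task-before-run order, canonicalizing on rewrite.
Note that the upstream BIDS grammar orders `task-` before `run-`; this
package deliberately renders `run-` first to match the canonical example
filenames it targets (`sub-YY_ses-1_run-1_task-XX_nirs.snirf`), while the
tolerant parser keeps both orders readable. Subject labels are stored
without the `sub-` prefix in memory; prefixes are a rendering concern.

## SNIRF subset and round-trip policy

Only `dataType` 1 (CW amplitude) is read or written; TD/FD payloads raise a
"not yet supported" error. In-file indices are 1-based per the SNIRF
convention; everything in memory is 0-based, and the boundary is crossed
only inside `nirsbids.snirf`. Time is stored as an explicit vector to
tolerate slightly irregular sampling; the nominal rate is the median
reciprocal inter-sample interval, and the declared `SamplingFrequency` must
agree with the rate derived from the time vector within 1 % (`NB201`).

Round trips are lossless by default: unrecognized `metaDataTags` are
preserved verbatim. Two pieces of the in-memory model have no native SNIRF
home and are handled as follows:

- **short-pair membership** is persisted in the custom tag
  `nirsbidsShortChannelPairs` (SNIRF permits arbitrary string tags); when the
  tag is absent, flags read as false;
- **event `response` text** has no stim-block representation; it survives
  only through `_events.tsv` and reads back as missing from SNIRF.

Stim block rows are (onset, duration, value) with value defaulting to 1.0.
HDF5 objects are created with `track_times` disabled, so repeated
conversions of identical inputs are byte-identical — conversion idempotence
is tested bytewise over whole trees.

## Sidecars and controlled redundancy

`_nirs.json` requires `TaskName`, `SamplingFrequency`, `NIRSChannelCount`,
`NIRSSourceOptodeCount`, `NIRSDetectorOptodeCount`; `ShortChannelCounts`,
`CapManufacturer` and `NIRSPlacementScheme` are recommended.
`ShortChannelCounts` counts short source-detector *pairs*, not
per-wavelength rows — the convention a practitioner uses when describing a
"24 long + 12 short channel" 2-wavelength device — and the converter and
validator enforce the same definition (`NB204`).

TSV dialect: tab-separated UTF-8, header first, `n/a` for missing values,
no quoting, `\n` newlines, shortest round-trippable numeric text
(wavelengths print as integers when integral). Every sidecar value is
computed from the SNIRF content at write time, so converter output satisfies
the redundancy rules by construction; the validator re-derives the same
quantities on read and flags any disagreement (`NB2xx`).

The events file is required exactly when the SNIRF file holds stimulus
blocks. `trial_type` is the stim condition name; per-event stim values
populate the `value` column. The optodes table and coordsystem document are
recommended as a *pair*: optodes without coordsystem is an ERROR (`NB106`,
a deliberate local strictness — the two files only make sense together),
while a missing optodes table alone is the WARNING the standard's
"recommended" language implies (`NB105`). Writing positions without a
declared coordinate frame is refused outright.

## Validator

Rules are namespaced NB0xx (dataset), NB1xx (naming/placement), NB2xx
(redundancy), NB3xx (coordinates); every finding carries a code from the
published catalogue, the rule's severity, a root-relative path and a
message. Issue lists are deterministic (sorted by path, then code); an empty
list means fully compliant *including recommendations*. Severity follows
the standard's own language: "must" is ERROR, "recommended/should" is
WARNING; `--strict` promotes warnings. Non-NIRS sibling directories
(`eeg/`, `physio/`, …) and `*_physio.*` files are ignored rather than
validated; `sourcedata/`, `code/`, `stimuli/` and `derivatives/` are
recognized containers. Demographic columns in `participants.tsv` pass
through unvalidated (no controlled vocabulary is imposed).

## Synthetic data generator

The generator's purpose is structural realism: trees that exercise every
rule, not physiologically faithful optics. What it emulates — multi-optode
montages with long (~30 mm) and short (8 mm) separations, two wavelengths
per pair, block-design tasks with named conditions, strictly positive noisy
intensities with physiological oscillations and a task response confined to
long channels. What it does not — photon transport, anatomical head
geometry, hemoglobin dynamics, motion artifacts, detector saturation. A
passing suite therefore demonstrates correct *data organization and
bookkeeping* on real-shaped datasets, not signal-processing performance on
real physiology.

**Geometry.** Optodes sit on a checkerboard grid with 30 mm pitch (adjacent
cells alternate source/detector, so nearest neighbours sit at the long
separation), lifted onto a sphere whose radius exceeds the grid extent by
20 mm — a scalp patch. Template-2D montages keep the flat coordinates. Long
pairs are chosen by a deterministic nearest-neighbour rule that first covers
every detector, then every uncovered source, then adds the closest remaining
pairs; short pairs add one dedicated detector 8 mm from a source, cycling
through sources. Separations are plausibility devices only — no validation
rule thresholds on distance.

**Signal.** Per channel, intensity is
`B · (1 + 0.02·sin(2π f_c t + φ) + 0.015·sin(2π·0.3 t + φ') + s·0.015·boxcar + ε)`
with baseline `B ~ U(0.5, 1.5)`, cardiac frequency `f_c ~ U(0.9, 1.1)` Hz, a
0.3 Hz Mayer-wave component, and uniform noise `ε ~ U(-0.01, 0.01)`. The
task boxcar appears in long channels only, with intensity *falling* at the
longest wavelength and rising at the others (the sign pattern of an
oxygenation response), at 1.5 % of baseline. Modulations sum to < 6 % of
baseline, so amplitudes are strictly positive for every seed. Randomness
uses one documented algorithm (numpy `default_rng`) with per-participant
substreams `SeedSequence([study_seed, participant_index])`; the study seed
is recorded in `dataset_description.json`'s `GeneratedBy` entry for
provenance.

**Blocks.** Conditions are presented round-robin: a lead-in of one
inter-block interval, then `n_blocks_per_condition` cycles of
(block, interval) per condition. Durations too short to fit the requested
blocks are rejected; the default duration is the requirement plus a 10 s
tail.

**Replica datasets.** Four parameter sets mirror published example datasets.
Printed parameters are honored exactly and measured back from the emitted
trees in `scripts/acceptance.py`:

| replica | participants | sources | detectors | short pairs | conditions |
|---|---|---|---|---|---|
| automatic_movements | 24 | (8) | (8) | 12 (24 long pairs) | (4) |
| motor_task | 5 | 8 | 8 | 8 | 3 |
| passive_auditory | 17 | 16 | 16 | 8 | 3 |
| audio_visual | 17 | 16 | 16 | 8 | 3 |

Parenthesized values are *not* printed in the source descriptions and are
package conventions, as are all long-pair counts for the motor/auditory/
audio-visual montages (20/40/40, chosen so the covering pairing uses every
printed source and detector), block timings, sampling rates (7.8 Hz motor,
10 Hz otherwise), and condition names. The movements dataset uses a
template-2D layout to exercise the `n/a`-z path; the others use measured 3-D
coordinates.

## Study manifest

`nirsbids convert` consumes a JSON manifest (schema in
`nirsbids/manifest.py`, validated with pydantic so violations report field
paths): study name/authors, the participant roster (extra demographic
columns pass through), one entry per run mapping a SNIRF path to its
entities, and optional extras routed to `sourcedata/`, `code/`, `stimuli/`
or sibling modality directories. Separate-device physiological recordings
are never injected into a SNIRF `aux` group; `attach_extra_data` refuses the
attempt and points to the proper convention.

## Problem sizes and numerical notes

The acceptance checks use 100 fuzzed study configurations (1-3 participants,
up to 4x4 optodes, 2-3 wavelengths, all three coordinate kinds, sessions and
run indices included), a 20-mutation corruption suite, 15 fuzzed round-trip
recordings, and 500 random entity tuples; the replica datasets are generated
at full size (e.g. all 24 movement participants). These sizes were chosen so
the whole acceptance run completes in tens of seconds while covering every
code path; the structural counts being measured are size-exact, not
statistical. Floating-point policy: data round-trips are bit-exact (float64
end to end); only the sampling rate is re-derived on read and compared at
1 % tolerance; TSV numeric cells use `repr`-shortest text, which float64
round-trips exactly.

## Known limitations

- CW amplitude only; no TD/FD payloads, no multi-run SNIRF files.
- Entities beyond subject/session/task/run (e.g. `acq-`) are not modeled.
- `derivatives/` content and stimulus files are placed, never inspected.
- The validator is NIRS-specific: it is not a replacement for the upstream
  modality-agnostic BIDS validator on mixed datasets.
- `_coordsystem.json` anatomical-landmark fields are treated as optional.
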