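# nirsbids

Organize, generate and validate **continuous-wave fNIRS datasets** in the
NIRS-BIDS layout: SNIRF data files arranged in the BIDS directory hierarchy
with JSON/TSV metadata sidecars.

Functional near-infrared spectroscopy measures cortical hemodynamics through
optical *channels*, each formed by a light-emitting **source** and a
photodetecting **detector** (jointly: *optodes*). Because the technique is
spectroscopic, every source-detector pair is measured at two or more nominal
wavelengths, and NIRS-BIDS defines a channel as *one optical signal at a
single wavelength*: a pair measured at 760 and 850 nm contributes two rows to
the channels table. Sharing such data reproducibly requires more than a file
format — it needs a fixed directory hierarchy, a filename grammar, and
machine-checkable metadata. That is what this toolkit implements, for
datasets whose runs are stored in the SNIRF (HDF5) container:

- **`nirsbids.snirf`** — a minimal CW SNIRF reader/writer. One run per file
  (the writer cannot produce, and the reader refuses, multi-run files);
  time-domain/frequency-domain payloads are detected and rejected rather
  than mangled; unknown `metaDataTags` survive round trips verbatim.
- **`nirsbids.model`** — the entity grammar
  `sub-<label>[_ses-<label>][_run-<k>]_task-<label>_<suffix>.<ext>` with a
  verified `format ∘ parse` round trip, plus the montage/channel/event types.
- **`nirsbids.convert`** — assembles recordings + study metadata into the
  tree: `dataset_description.json` and `participants.tsv` at the root, and
  per run the `.snirf` file with `_nirs.json`, `_channels.tsv`,
  `_optodes.tsv`/`_coordsystem.json` (when positions exist) and
  `_events.tsv` (when the run has stimulus blocks). Sidecar values are
  *derived from the SNIRF content* — this controlled redundancy makes common
  metadata readable without opening HDF5.
- **`nirsbids.validate`** — a rule catalogue (`NB0xx` dataset, `NB1xx`
  naming, `NB2xx` SNIRF/sidecar redundancy, `NB3xx` coordinates) producing
  severity-graded findings; required content ("must") is ERROR, recommended
  content ("should") is WARNING.
- **`nirsbids.synth`** — a deterministic generator of complete synthetic
  studies (montage geometry, positive block-design intensity signals,
  events), including replicas of four published example datasets whose
  printed structural parameters it reproduces exactly.

Short-separation channels — closely spaced pairs (~8 mm here) that sample
scalp rather than brain — are first-class: flagged per row in the
`short_channel` column and counted **per pair** in the `ShortChannelCounts`
sidecar field (a 2-wavelength device with 12 short pairs reports 12, not 24).

## Worked example

```python
from nirsbids import generate_study, replica_spec, validate_dataset

spec = replica_spec("motor_task", seed=1)       # 5 participants, 8 sources,
summary = generate_study(spec, "motor-bids")    # 8 detectors + 8 short dets
print(len(summary.files), "files for", len(summary.subjects), "subjects")
print("findings:", len(validate_dataset("motor-bids")))
```

prints

```
32 files for 5 subjects
findings: 0
```

32 files = 2 study-level files + 5 subjects x 6 run files; 0 findings means
every rule passes, recommendations included. Each subject's channels table
has 56 rows — (20 long + 8 short) pairs x 2 wavelengths — and its events
table holds the three conditions of the finger-tapping block design.
More narrative scripts live in `examples/`.

The same operations are available from a shell:

```bash
nirsbids example motor_task --out motor-bids --seed 1
nirsbids validate motor-bids --json-report report.json   # exit 0 iff no ERRORs
nirsbids convert manifest.json out-bids                  # see docs/methods.md
```

Exit codes: 0 no errors, 1 validation errors, 2 usage/input errors;
`--strict` promotes warnings to errors.

## Scope

Continuous-wave amplitude data only; time-domain and frequency-domain SNIRF
payloads are recognized and refused. The validator checks NIRS content only —
sibling modality directories (`eeg/`, …) may coexist but are not validated.
Hemoglobin-concentration conversion (modified Beer-Lambert) is out of scope:
this is a data-organization toolkit, not an analysis package. See
`docs/methods.md` for the full model, conventions and limitations.
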