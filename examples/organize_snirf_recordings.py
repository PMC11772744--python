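"""Organize loose SNIRF recordings into a NIRS-BIDS tree.

Builds two single-run SNIRF files (here fabricated; normally exported by your
acquisition software), then assembles them with study metadata into the BIDS
hierarchy and prints what was written.  The sidecars deliberately duplicate
SNIRF-internal metadata (controlled redundancy) so they are filled from the
recordings themselves.
"""

import tempfile
from pathlib import Path

from nirsbids import (
    BidsEntities,
    StudyDescription,
    attach_extra_data,
    build_dataset,
    generate_recording,
    read_snirf,
    write_snirf,
)
from nirsbids.synth import MontageSpec, StudySpec, TaskSpec

work = Path(tempfile.mkdtemp())

# two participants' recordings: 4 long + 2 short pairs, 760/850 nm
spec = StudySpec(
    name="demo",
    n_participants=2,
    montage_spec=MontageSpec(n_sources=2, n_detectors=2, long_pairs=4, short_pairs=2),
    task_spec=TaskSpec(name="tapping", conditions=("tap", "rest")),
    fs=10.0,
    seed=42,
)
for i in range(2):
    write_snirf(generate_recording(spec, i), work / f"participant{i + 1}.snirf")

runs = [
    (read_snirf(work / f"participant{i + 1}.snirf"), BidsEntities(subject=f"{i + 1:02d}", task="tapping"))
    for i in range(2)
]
study = StudyDescription(
    name="Finger tapping demo",
    authors=["A. Researcher"],
    participants=[
        {"participant_id": "sub-01", "age": 27, "sex": "F"},
        {"participant_id": "sub-02", "age": 31, "sex": "M"},
    ],
)
root = work / "bids"
summary = build_dataset(runs, study, root)
attach_extra_data(root, "code", "# conversion script\n", dest_name="convert.py")

print(f"{summary.n_runs} runs -> {len(summary.files)} files under {root}")
for f in summary.files:
    print(" ", f)
# Each run contributes the .snirf data file plus _nirs.json (acquisition
# setup), _channels.tsv (one row per wavelength of each source-detector
# pair: 6 pairs x 2 wavelengths = 12 rows), _optodes.tsv/_coordsystem.json
# (probe geometry) and _events.tsv (block onsets/durations/conditions).
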