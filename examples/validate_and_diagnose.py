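"""Validate a dataset, break it on purpose, and read the diagnoses.

Shows the severity grading: deleting a *recommended* file (optodes table)
yields a WARNING, corrupting *required* redundant metadata yields an ERROR
with the rule code and the offending path.
"""

import tempfile
from pathlib import Path

from nirsbids import generate_study, validate_dataset
from nirsbids.sidecars import read_json, write_json
from nirsbids.testing import small_study_spec

root = Path(tempfile.mkdtemp()) / "dataset"
generate_study(small_study_spec(seed=3), root)
print("fresh tree findings:", len(validate_dataset(root)))

# delete the recommended optodes/coordsystem pair -> WARNING only
next(root.glob("sub-01/nirs/*_optodes.tsv")).unlink()
next(root.glob("sub-01/nirs/*_coordsystem.json")).unlink()

# corrupt the redundant SamplingFrequency copy in the JSON sidecar -> ERROR
sidecar = next(root.glob("sub-02/nirs/*_nirs.json"))
doc = read_json(sidecar)
doc["SamplingFrequency"] = doc["SamplingFrequency"] * 2
write_json(doc, sidecar)

for issue in validate_dataset(root):
    print(f"{issue.severity.value:7s} {issue.code} {issue.path}")
    print(f"        {issue.message}")
# NB105 (WARNING) flags the missing recommended table; NB201 (ERROR) flags
# the mismatch between the sidecar value and the rate derived from the SNIRF
# time vector -- the controlled redundancy the validator cross-checks.
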