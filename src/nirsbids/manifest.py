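"""The study manifest: one JSON document driving a whole conversion.

Schema (validated with pydantic; unknown keys are rejected with field paths)::

    {
      "name": "My fNIRS study",              // required
      "bids_version": "1.8.0",               // optional
      "authors": ["A. Author"],              // optional
      "acknowledgements": "...",             // optional
      "participants": [                      // required; extra demographic
        {"participant_id": "sub-01", "age": 23, "sex": "F"}   // columns allowed
      ],
      "runs": [                              // required, >= 1
        {"snirf": "rel/or/abs/path.snirf",
         "subject": "01", "task": "tapping",
         "session": null, "run": null}
      ],
      "extras": [                            // optional sourcedata/code/stimuli
        {"kind": "code", "path": "convert.py", "subject": null, "dest_name": null}
      ]
    }

Relative ``snirf``/``path`` entries are resolved against the manifest's own
directory.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .model import BidsEntities, NirsBidsError


class ParticipantRow(BaseModel):
    model_config = ConfigDict(extra="allow")

    participant_id: str = Field(pattern=r"^sub-[a-zA-Z0-9]+$")


class RunEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    snirf: str
    subject: str = Field(pattern=r"^[a-zA-Z0-9]+$")
    task: str = Field(pattern=r"^[a-zA-Z0-9]+$")
    session: Optional[str] = Field(default=None, pattern=r"^[a-zA-Z0-9]+$")
    run: Optional[int] = Field(default=None, ge=1)

    def entities(self) -> BidsEntities:
        return BidsEntities(subject=self.subject, task=self.task, session=self.session, run=self.run)


class ExtraEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: str
    path: str
    subject: Optional[str] = None
    dest_name: Optional[str] = None


class StudyManifest(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    bids_version: str = "1.8.0"
    authors: List[str] = Field(default_factory=list)
    acknowledgements: Optional[str] = None
    participants: List[ParticipantRow]
    runs: List[RunEntry] = Field(min_length=1)
    extras: List[ExtraEntry] = Field(default_factory=list)


class ManifestError(NirsBidsError):
    """The manifest failed schema validation; the message lists field paths."""


def load_manifest(path) -> StudyManifest:
    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise ManifestError(f"cannot read manifest {path}: {exc}") from exc
    try:
        return StudyManifest.model_validate(raw)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ManifestError(
            f"manifest {path} violates the study-manifest schema:\n" + "\n".join(lines)
        ) from exc


def resolve_path(manifest_path, entry_path: str) -> Path:
    p = Path(entry_path)
    return p if p.is_absolute() else Path(manifest_path).parent / p
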