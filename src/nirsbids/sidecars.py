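"""Sidecar documents for one run and their on-disk TSV/JSON dialect.

The sidecars deliberately duplicate metadata already present in the SNIRF
file (sampling frequency, channel and optode tables, short-channel flags);
this controlled redundancy makes the commonly queried metadata readable
without opening the HDF5 container, and the validator cross-checks the two
copies against each other.

TSV dialect: tab-separated, UTF-8, header row first, missing values written
as the literal ``n/a``, no quoting, ``\\n`` newlines.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .model import NA, Montage, NirsBidsError, PositionKind

#: Required fields of the ``*_nirs.json`` sidecar.
REQUIRED_NIRS_JSON_FIELDS = (
    "TaskName",
    "SamplingFrequency",
    "NIRSChannelCount",
    "NIRSSourceOptodeCount",
    "NIRSDetectorOptodeCount",
)

#: Recommended (non-mandatory) fields of the ``*_nirs.json`` sidecar.
RECOMMENDED_NIRS_JSON_FIELDS = (
    "ShortChannelCounts",
    "CapManufacturer",
    "NIRSPlacementScheme",
)

CHANNELS_COLUMNS = [
    "name",
    "type",
    "source",
    "detector",
    "wavelength_nominal",
    "sampling_frequency",
    "short_channel",
]

OPTODES_COLUMNS = ["name", "type", "x", "y", "z"]

EVENTS_COLUMNS = ["onset", "duration", "trial_type", "value", "response"]


def _fmt_cell(value) -> str:
    """Shortest round-trippable text for one TSV cell."""
    if value is None:
        return NA
    if isinstance(value, float):
        if math.isnan(value):
            return NA
        if value == int(value) and abs(value) < 1e15:
            return str(int(value))
        return repr(value)
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a table in the package's TSV dialect."""
    lines = ["\t".join(df.columns)]
    for row in df.itertuples(index=False):
        lines.append("\t".join(_fmt_cell(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_tsv(path) -> pd.DataFrame:
    """Read a TSV keeping every cell as text; ``n/a`` stays literal."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_json(doc: dict, path) -> None:
    Path(path).write_text(
        json.dumps(doc, indent=4, ensure_ascii=False) + "\n", encoding="utf-8"
    )


def read_json(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


@dataclass
class SidecarSet:
    """The full set of metadata documents describing one run.

    ``optodes_table``/``coordsystem`` are ``None`` when the montage carries
    no positions, ``events_table`` is ``None`` when the run has no stimulus
    blocks.  A *draft* set (as produced from a SNIRF file alone) leaves the
    study-level fields such as ``TaskName`` empty for the converter to fill.
    """

    nirs_json: dict = field(default_factory=dict)
    channels_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    optodes_table: Optional[pd.DataFrame] = None
    coordsystem: Optional[dict] = None
    events_table: Optional[pd.DataFrame] = None

    def validate(self) -> None:
        n = self.nirs_json.get("NIRSChannelCount")
        if n is not None and len(self.channels_table) != n:
            raise NirsBidsError(
                f"channels table has {len(self.channels_table)} rows but "
                f"NIRSChannelCount is {n}"
            )
        scc = self.nirs_json.get("ShortChannelCounts")
        if scc is not None:
            if short_pair_count(self.channels_table) != scc:
                raise NirsBidsError(
                    "ShortChannelCounts disagrees with the short_channel column "
                    "(counted per source-detector pair)"
                )


def short_pair_count(channels_table: pd.DataFrame) -> int:
    """Number of distinct source-detector *pairs* flagged short.

    The sidecar field ``ShortChannelCounts`` counts pairs, not per-wavelength
    rows: a 2-wavelength device with 12 short pairs reports 12, not 24.
    """
    if channels_table.empty:
        return 0
    sub = channels_table[
        channels_table["short_channel"].astype(str).str.lower().isin(("true", "1"))
    ]
    return len(sub[["source", "detector"]].drop_duplicates())


def channels_table_from_montage(montage: Montage) -> pd.DataFrame:
    rows = [
        {
            "name": ch.name,
            "type": ch.channel_type.value,
            "source": ch.source_label,
            "detector": ch.detector_label,
            "wavelength_nominal": ch.wavelength_nominal,
            "sampling_frequency": ch.sampling_frequency,
            "short_channel": ch.short_channel,
        }
        for ch in montage.channels
    ]
    return pd.DataFrame(rows, columns=CHANNELS_COLUMNS)


def optodes_table_from_montage(montage: Montage) -> Optional[pd.DataFrame]:
    """Optode table, or ``None`` when the montage has no positions.

    For 2-D template layouts the third coordinate column holds the missing
    marker ``n/a`` in every row.
    """
    kind = montage.position_kind
    if kind is PositionKind.ABSENT:
        return None
    rows = []
    for o in montage.optodes:
        x, y = o.position[0], o.position[1]
        z = o.position[2] if kind is PositionKind.MEASURED_3D else None
        rows.append({"name": o.label, "type": o.role.value, "x": x, "y": y, "z": z})
    return pd.DataFrame(rows, columns=OPTODES_COLUMNS)


def coordsystem_from_montage(montage: Montage) -> Optional[dict]:
    if montage.position_kind is PositionKind.ABSENT:
        return None
    doc = {
        "NIRSCoordinateSystem": montage.coordinate_frame or "Other",
        "NIRSCoordinateUnits": montage.unit,
    }
    if montage.position_kind is PositionKind.TEMPLATE_2D:
        doc["NIRSCoordinateSystemDescription"] = (
            "Flattened 2-D template layout; the z coordinate is not available "
            "and is recorded as n/a in the optodes table."
        )
    return doc


def events_table_from_records(events) -> pd.DataFrame:
    """Events table sorted by onset; optional columns kept only when used."""
    rows = [
        {
            "onset": ev.onset,
            "duration": ev.duration,
            "trial_type": ev.trial_type,
            "value": ev.value,
            "response": ev.response,
        }
        for ev in events
    ]
    df = pd.DataFrame(rows, columns=EVENTS_COLUMNS)
    df = df.sort_values(["onset", "trial_type"], kind="stable").reset_index(drop=True)
    if df["response"].isna().all():
        df = df.drop(columns=["response"])
    if "value" in df.columns and df["value"].isna().all():
        df = df.drop(columns=["value"])
    return df
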