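"""Standardized report emission: human-readable text and machine-readable CSV.

The text report groups features by category and, for the cortical and
subcortical profiles, lists only structures with a non-zero overlap to keep
the document readable. The CSV always carries the complete feature set
(one row per patient, one column per feature plus the identifier) so it can
feed follow-up statistical analyses.
"""

from __future__ import annotations

import datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .features import TumorFeatureRecord

_RULE = "-" * 60


def render_text_report(record: TumorFeatureRecord,
                       timestamp: str | None = None) -> str:
    """Render a record as the standardized text report.

    Percent, mL and mm values use two decimals; structure sections omit
    zero-overlap entries. The output is deterministic apart from the
    timestamp header.
    """
    if timestamp is None:
        timestamp = datetime.datetime.now().isoformat(timespec="seconds")
    lines = [
        "Standardized tumor feature report",
        _RULE,
        f"Patient:   {record.patient_id}",
        f"Generated: {timestamp}",
        f"Software:  glioprofile {__version__}",
        _RULE,
    ]
    if not record.has_tumor:
        lines += ["", "No tumor remained after mask refinement.", ""]
        return "\n".join(lines)

    lines += [
        "",
        "Volume",
        f"  Patient space: {record.volume_patient_ml:.2f} mL",
        f"  MNI space:     {record.volume_mni_ml:.2f} mL",
        "",
        "Laterality",
        f"  Left hemisphere:  {record.left_pct:.2f} %",
        f"  Right hemisphere: {record.right_pct:.2f} %",
        f"  Midline crossing: {record.midline_crossing}",
        "",
        "Multifocality",
        f"  Multifocal:  {record.multifocal}",
        f"  Focus count: {record.focus_count}",
        f"  Largest satellite distance: {record.satellite_distance_mm:.2f} mm",
        "",
        "Resectability",
        f"  Expected residual volume: {record.expected_residual_ml:.2f} mL",
        f"  Resectability index:      {record.resectability_index:.4f}",
        "",
        "Cortical structure profile (non-zero overlaps)",
    ]
    for name, pct in record.cortical_overlap_pct.items():
        if pct > 0:
            lines.append(f"  {name}: {pct:.2f} %")
    lines += ["", "Subcortical structure profile (non-zero overlaps)"]
    for name, pct in record.subcortical_overlap_pct.items():
        if pct > 0:
            lines.append(f"  {name}: {pct:.2f} % "
                         f"(distance {record.subcortical_distance_mm[name]:.2f} mm)")
    lines.append("")
    return "\n".join(lines)


def write_text_report(record: TumorFeatureRecord, path: str | Path,
                      timestamp: str | None = None) -> str:
    text = render_text_report(record, timestamp)
    Path(path).write_text(text)
    return text


def _csv_value(value: object) -> object:
    if isinstance(value, bool):
        return int(value)
    return value


def records_to_frame(records: Sequence[TumorFeatureRecord],
                     names: Sequence[str] | None = None) -> pd.DataFrame:
    """One row per patient, 1 + 233 columns; booleans as 1/0.

    ``names`` fixes the column registry (needed to emit a header-only file
    for zero records); with records present it must match their registry.
    """
    if records:
        registry = list(records[0].to_dict())
        for r in records[1:]:
            if list(r.to_dict()) != registry:
                raise ValueError("records do not share a feature registry")
        if names is not None and list(names) != registry:
            raise ValueError("requested registry does not match the records")
        names = registry
    else:
        names = list(names) if names is not None else []
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id}
        row.update({k: _csv_value(v) for k, v in r.to_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id"] + names)


def write_csv(records: Iterable[TumorFeatureRecord], path: str | Path,
              names: Sequence[str] | None = None) -> pd.DataFrame:
    """Write the complete feature table (no non-null filtering) as CSV."""
    frame = records_to_frame(list(records), names)
    frame.to_csv(path, index=False)
    return frame
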