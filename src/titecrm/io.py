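"""Reading and writing patient-record tables.

The on-disk format is a CSV with header
``id,enrol_time,schedule,window,follow_up,dlt,t_dlt`` (times in weeks,
1-based schedule index, ``t_dlt`` empty when ``dlt`` is 0), or the
equivalent JSON list of objects.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import pandas as pd

from .errors import ValidationError
from .model import PatientRecord

PATIENT_COLUMNS = ["id", "enrol_time", "schedule", "window", "follow_up", "dlt", "t_dlt"]


def _record_from_row(row: dict) -> PatientRecord:
    t_dlt = row.get("t_dlt")
    if t_dlt is not None and (t_dlt == "" or pd.isna(t_dlt)):
        t_dlt = None
    return PatientRecord(
        id=str(row["id"]),
        enrol_time=float(row["enrol_time"]),
        schedule=int(row["schedule"]),
        window=float(row["window"]),
        follow_up=float(row["follow_up"]),
        dlt=int(row["dlt"]),
        t_dlt=None if t_dlt is None else float(t_dlt),
    )


def read_patients(path) -> List[PatientRecord]:
    """Load patient records from a CSV or JSON file (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise ValidationError("patient JSON must be a list of objects")
    else:
        df = pd.read_csv(path)
        missing = set(PATIENT_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"patient CSV missing columns: {sorted(missing)}")
        rows = df.to_dict(orient="records")
    return [_record_from_row(r) for r in rows]


def write_patients(records: Sequence[PatientRecord], path) -> None:
    """Write patient records as CSV or JSON (by extension)."""
    path = Path(path)
    rows = [
        {
            "id": r.id,
            "enrol_time": r.enrol_time,
            "schedule": r.schedule,
            "window": r.window,
            "follow_up": r.follow_up,
            "dlt": r.dlt,
            "t_dlt": r.t_dlt,
        }
        for r in records
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=2))
    else:
        df = pd.DataFrame(rows, columns=PATIENT_COLUMNS)
        df.to_csv(path, index=False)
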