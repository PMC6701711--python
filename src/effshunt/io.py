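"""CSV input/output for ABG records and results.

Canonical columns: patient_id, timestamp (ISO-8601), fio2 (fraction),
pao2, paco2 (kPa), ph, hb (g/l, blank allowed), temperature (Celsius,
blank allowed), ventilated (bool). ``units="mmHg"`` converts tensions at
this boundary only — everything internal is kPa.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .indices import ABGRecord
from .odc import MMHG_PER_KPA

REQUIRED_COLUMNS = ["patient_id", "timestamp", "fio2", "pao2", "paco2", "ph"]
TENSION_COLUMNS = ["pao2", "paco2"]


def _unit_factor(units: str) -> float:
    if units.lower() in ("kpa",):
        return 1.0
    if units.lower() in ("mmhg", "torr"):
        return MMHG_PER_KPA
    raise InvalidInputError(f"unknown units {units!r} (use 'kPa' or 'mmHg')")


def records_to_frame(records: Sequence[ABGRecord], units: str = "kPa") -> pd.DataFrame:
    f = _unit_factor(units)
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "timestamp": [r.timestamp.isoformat() for r in records],
            "fio2": [r.fio2 for r in records],
            "pao2": [r.pao2 * f for r in records],
            "paco2": [r.paco2 * f for r in records],
            "ph": [r.ph for r in records],
            "hb": [r.hb for r in records],
            "temperature": [r.temperature for r in records],
            "ventilated": [r.ventilated for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame, units: str = "kPa") -> List[ABGRecord]:
    f = _unit_factor(units)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"missing required columns: {missing}")
    records = []
    for row in frame.itertuples(index=False):
        hb = getattr(row, "hb", None)
        temp = getattr(row, "temperature", None)
        vent = getattr(row, "ventilated", True)
        records.append(
            ABGRecord(
                patient_id=str(row.patient_id),
                timestamp=pd.Timestamp(row.timestamp).to_pydatetime(),
                fio2=float(row.fio2),
                pao2=float(row.pao2) / f,
                paco2=float(row.paco2) / f,
                ph=float(row.ph),
                hb=None if hb is None or (isinstance(hb, float) and np.isnan(hb)) else float(hb),
                temperature=None
                if temp is None or (isinstance(temp, float) and np.isnan(temp))
                else float(temp),
                ventilated=bool(vent) if not pd.isna(vent) else True,
            )
        )
    return records


def read_abg_csv(path, units: str = "kPa") -> List[ABGRecord]:
    return frame_to_records(pd.read_csv(path), units=units)


def write_abg_csv(records: Sequence[ABGRecord], path, units: str = "kPa") -> None:
    records_to_frame(records, units=units).to_csv(path, index=False)
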