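"""Tabular I/O: validated parsing of cast-measurement tables.

A cast table is a comma-separated UTF-8 file with a header, one row per
patient x jaw x side x timepoint.  Required columns: patient_id, jaw
(upper|lower), side (left|right), timepoint (T0|T1), L, W (mm).  Optional:
AL_measured (mm).  All lengths are millimetres.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

__all__ = ["CastTableRow", "CastTableError", "parse_cast_table"]

REQUIRED_COLUMNS = ("patient_id", "jaw", "side", "timepoint", "L", "W")
OPTIONAL_COLUMNS = ("AL_measured",)


class CastTableError(ValueError):
    """Malformed cast table; the message names the offending line and constraint."""


@dataclass(frozen=True)
class CastTableRow:
    patient_id: str
    jaw: str
    side: str
    timepoint: str
    L: float
    W: float
    AL_measured: Optional[float] = None


def _fail(line: int, msg: str) -> None:
    raise CastTableError(f"line {line}: {msg}")


def parse_cast_table(path) -> List[CastTableRow]:
    """Parse and validate a cast-measurement CSV.

    Rejects missing columns, non-numeric or out-of-range measurements
    (L < 0, W <= 0), empty identifiers and duplicate
    (patient, jaw, side, timepoint) keys, naming the offending line.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CastTableError("empty file: a header line is required")
        missing = set(REQUIRED_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise CastTableError(f"missing required columns: {sorted(missing)}")

        rows: List[CastTableRow] = []
        seen = set()
        for lineno, rec in enumerate(reader, start=2):
            pid = (rec.get("patient_id") or "").strip()
            jaw = (rec.get("jaw") or "").strip()
            side = (rec.get("side") or "").strip()
            tp = (rec.get("timepoint") or "").strip()
            if not pid:
                _fail(lineno, "patient_id must be non-empty")
            if jaw not in ("upper", "lower"):
                _fail(lineno, f"jaw must be 'upper' or 'lower', got {jaw!r}")
            if side not in ("left", "right"):
                _fail(lineno, f"side must be 'left' or 'right', got {side!r}")
            if tp not in ("T0", "T1"):
                _fail(lineno, f"timepoint must be 'T0' or 'T1', got {tp!r}")

            def num(col: str, required: bool = True) -> Optional[float]:
                raw = (rec.get(col) or "").strip()
                if raw == "":
                    if required:
                        _fail(lineno, f"column {col!r} is empty")
                    return None
                try:
                    return float(raw)
                except ValueError:
                    _fail(lineno, f"column {col!r} must be numeric, got {raw!r}")

            L = num("L")
            W = num("W")
            al = num("AL_measured", required=False) if "AL_measured" in reader.fieldnames else None
            if L < 0:
                _fail(lineno, f"sagittal depth L must be >= 0, got {L}")
            if W <= 0:
                _fail(lineno, f"half arch width W must be > 0, got {W}")
            key = (pid, jaw, side, tp)
            if key in seen:
                _fail(lineno, f"duplicate key (patient, jaw, side, timepoint) = {key}")
            seen.add(key)
            rows.append(
                CastTableRow(
                    patient_id=pid, jaw=jaw, side=side, timepoint=tp, L=L, W=W, AL_measured=al
                )
            )
    return rows
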