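"""Readers and writers for the long-format germination tables.

One CSV row is one dish at one scoring time:

    dish,temperature_C,time_d,tr_count,er_count,dish_size,treatment_id

Counts are cumulative.  The reader validates every row and reports
problems with the offending line number.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd

from .simulate import GerminationRecord

__all__ = [
    "COLUMNS",
    "records_to_frame",
    "frame_to_records",
    "read_germination_csv",
]

COLUMNS = ["dish", "temperature_C", "time_d", "tr_count", "er_count",
           "dish_size", "treatment_id"]


def records_to_frame(records: Sequence[GerminationRecord]) -> pd.DataFrame:
    """Tabulate records (empty frame with the right columns if none)."""
    if not records:
        return pd.DataFrame(columns=COLUMNS)
    frame = pd.DataFrame([
        {c: getattr(r, c) for c in COLUMNS} for r in records])
    return frame[COLUMNS]


def frame_to_records(frame: pd.DataFrame, *,
                     source: str = "<frame>") -> list[GerminationRecord]:
    """Validate a tidy frame row by row into records.

    Raises ``ValueError`` naming ``source`` and the (1-based, header
    included) line number of the first malformed row.
    """
    missing = [c for c in COLUMNS if c not in frame.columns and
               c != "treatment_id"]
    if missing:
        raise ValueError(f"{source}: missing columns {missing}")
    records = []
    for pos, (_, row) in enumerate(frame.iterrows()):
        line = pos + 2  # header is line 1
        try:
            records.append(GerminationRecord(
                dish=str(row["dish"]),
                temperature_C=float(row["temperature_C"]),
                time_d=float(row["time_d"]),
                tr_count=int(row["tr_count"]),
                er_count=int(row["er_count"]),
                dish_size=int(row["dish_size"]),
                treatment_id=str(row.get("treatment_id", "water")),
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{source}, line {line}: {exc}") from exc
    _check_monotone(records, source)
    return records


def _check_monotone(records: list[GerminationRecord], source: str) -> None:
    """Cumulative counts within a dish must be non-decreasing in time."""
    frame = records_to_frame(records)
    for dish, grp in frame.groupby("dish"):
        grp = grp.sort_values("time_d")
        if (grp["tr_count"].diff().fillna(0) < 0).any() or \
                (grp["er_count"].diff().fillna(0) < 0).any():
            raise ValueError(
                f"{source}: cumulative counts decrease over time in dish "
                f"{dish!r}")


def read_germination_csv(path: str | Path) -> list[GerminationRecord]:
    """Read and validate a germination scoring CSV.

    Returns an empty list (with a warning) for a file that has a header
    but no rows.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.empty:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
        return []
    return frame_to_records(frame, source=str(path))
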