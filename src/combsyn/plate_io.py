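"""Plate CSV reading/writing.

One well per row (long/tidy layout), columns::

    plate_id, well, cell_line, time_h, drug_a, dose_a_uM, drug_b, dose_b_uM,
    total_cells, dead_cells

Doses are non-negative reals in μM; counts are non-negative (integers for
measured or sampled plates; expectation-mode simulated plates may carry
fractional expected counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import PlateSchemaError, PlateValidationError
from .median_effect import WellRecord

__all__ = ["REQUIRED_COLUMNS", "PlateTable", "read_plate_csv", "write_plate_csv",
           "plate_from_wells"]

REQUIRED_COLUMNS = (
    "plate_id", "well", "cell_line", "time_h",
    "drug_a", "dose_a_uM", "drug_b", "dose_b_uM",
    "total_cells", "dead_cells",
)


@dataclass(frozen=True)
class PlateTable:
    """A validated plate: well records plus per-row metadata."""

    frame: pd.DataFrame

    def records(self) -> list[WellRecord]:
        return [
            WellRecord(
                drug_a_dose=row.dose_a_uM,
                drug_b_dose=row.dose_b_uM,
                total_cells=row.total_cells,
                dead_cells=row.dead_cells,
                well_label=str(row.well),
            )
            for row in self.frame.itertuples()
        ]

    def __len__(self) -> int:
        return len(self.frame)


def _validate(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PlateSchemaError(f"{source}: missing required columns {missing}")
    df = df.copy()
    numeric = ["dose_a_uM", "dose_b_uM", "total_cells", "dead_cells", "time_h"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    problems: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        well = row["well"]
        if row[numeric].isna().any():
            problems.append(f"line {line} (well {well}): non-numeric field")
            continue
        if row.dose_a_uM < 0 or row.dose_b_uM < 0:
            problems.append(f"line {line} (well {well}): negative dose")
        if row.total_cells <= 0:
            problems.append(f"line {line} (well {well}): total_cells must be > 0")
        elif not 0 <= row.dead_cells <= row.total_cells:
            problems.append(
                f"line {line} (well {well}): dead_cells outside [0, total_cells]"
            )
    if problems:
        raise PlateValidationError(f"{source}: " + "; ".join(problems))
    return df


def read_plate_csv(path: str | Path) -> PlateTable:
    """Read and validate a plate CSV; malformed rows are reported by line number."""
    path = Path(path)
    df = pd.read_csv(path)
    return PlateTable(_validate(df, str(path)))


def write_plate_csv(table: PlateTable, path: str | Path) -> None:
    """Write a plate table; inverse of :func:`read_plate_csv`."""
    table.frame.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))


def plate_from_wells(
    wells: Sequence[WellRecord],
    plate_id: str,
    cell_line: str,
    time_h: float,
    drug_a: str,
    drug_b: str = "",
) -> PlateTable:
    """Assemble a PlateTable from well records plus shared metadata."""
    rows = [
        {
            "plate_id": plate_id,
            "well": w.well_label or f"w{i}",
            "cell_line": cell_line,
            "time_h": time_h,
            "drug_a": drug_a,
            "dose_a_uM": w.drug_a_dose,
            "drug_b": drug_b,
            "dose_b_uM": w.drug_b_dose,
            "total_cells": w.total_cells,
            "dead_cells": w.dead_cells,
        }
        for i, w in enumerate(wells)
    ]
    return PlateTable(pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)))
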