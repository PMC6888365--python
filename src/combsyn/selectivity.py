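"""Selectivity indices between cell lines, with censored-IC50 propagation.

SI = IC50(comparator line) / IC50(target line).  When the comparator IC50 is
right-censored (reported as ">value", i.e. the drug never reached 50% kill at
the top tested dose) the SI is itself a lower bound and is reported as ">SI";
an SI below 2 flags general (unselective) toxicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import InvalidInputError, UndeterminedSelectivityError

__all__ = [
    "CensoredIC50",
    "SelectivityIndex",
    "selectivity_index",
    "flag_general_toxicity",
    "selectivity_matrix",
]


@dataclass(frozen=True)
class CensoredIC50:
    """An IC50 in μM, possibly right-censored (true IC50 exceeds ``value``)."""

    value: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value) and self.value > 0):
            raise InvalidInputError(f"IC50 must be a positive number, got {self.value!r}")

    def __str__(self) -> str:
        return f">{self.value:g}" if self.censored else f"{self.value:g}"


@dataclass(frozen=True)
class SelectivityIndex:
    """A selectivity index; ``censored`` means the true SI exceeds ``value``."""

    value: float
    censored: bool = False

    def rounded(self, ndigits: int = 2) -> float:
        return round(self.value, ndigits)

    def __str__(self) -> str:
        prefix = ">" if self.censored else ""
        return f"{prefix}{self.value:.2f}"


def selectivity_index(
    ic50_reference: CensoredIC50, ic50_target: CensoredIC50
) -> SelectivityIndex:
    """SI = reference IC50 / target IC50, propagating censoring as a bound.

    A censored reference gives a lower bound on SI (reported ">SI").  A
    censored target alone, or both censored, leaves SI unbounded in the
    direction of interest and raises :class:`UndeterminedSelectivityError` —
    treating the censoring limit as an exact value would misreport selectivity.
    """
    if ic50_target.censored:
        raise UndeterminedSelectivityError(
            "target IC50 is censored; only an upper bound on SI would exist"
            if not ic50_reference.censored
            else "both IC50s are censored; SI is undetermined"
        )
    return SelectivityIndex(
        value=ic50_reference.value / ic50_target.value,
        censored=ic50_reference.censored,
    )


def flag_general_toxicity(si: SelectivityIndex) -> bool:
    """True when the treatment shows general toxicity (SI < 2, strict).

    For a censored SI the bound itself is compared: a bound below 2 cannot
    rule general toxicity out, so it is flagged.
    """
    return si.value < 2.0


def selectivity_matrix(
    ic50s: Mapping[str, Mapping[str, CensoredIC50]],
    target_line: str,
    comparator_lines: list[str] | None = None,
) -> pd.DataFrame:
    """Selectivity matrix: rows = treatments, columns = comparator cell lines.

    ``ic50s`` maps treatment -> cell line -> IC50.  Each cell holds the SI of
    the comparator line relative to ``target_line``, formatted to 2 decimals
    with a ">" prefix for censored bounds; undetermined cells show "n.d.".
    """
    out: dict[str, dict[str, str]] = {}
    for treatment, by_line in ic50s.items():
        target = by_line[target_line]
        lines = comparator_lines or [ln for ln in by_line if ln != target_line]
        row = {}
        for line in lines:
            try:
                row[line] = str(selectivity_index(by_line[line], target))
            except UndeterminedSelectivityError:
                row[line] = "n.d."
        out[treatment] = row
    return pd.DataFrame.from_dict(out, orient="index")
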