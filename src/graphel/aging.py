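"""Accelerated-aging lifetime arithmetic and soak-test summary tables.

Elevated-temperature soak testing compresses time: chemical degradation
rates roughly double for every 10 °C above the reference temperature,
so a device held at temperature T accrues equivalent lifetime at a rate

    f = 2^((T − T_ref) / 10)

relative to T_ref (37 °C by default, mouse body temperature).  A soak at
87 °C therefore ages a device 32× faster, and 30 days in the bath stand
for 960 equivalent days in vivo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AgingCondition",
    "ArrayRecord",
    "aging_factor",
    "equivalent_lifetime",
    "build_summary_table",
    "reference_records",
    "DAYS_PER_YEAR",
    "FAILURE_MECHANISMS",
]

#: Julian year; 365 and 365.25 give identical 2-decimal results for all
#: soak durations up to 30 days at factor 32.
DAYS_PER_YEAR = 365.25

FAILURE_MECHANISMS = ("none", "minor_permeation", "crack_electrode", "crack_wire")

_MECHANISM_LABELS = {
    "none": "No failure",
    "minor_permeation": "Minor PBS permeation",
    "crack_electrode": "Cracks over electrode",
    "crack_wire": "Cracks over wire",
}


@dataclass(frozen=True)
class AgingCondition:
    """Soak temperature and reference temperature, °C."""

    t_device: float
    t_ref: float = 37.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t_device) and math.isfinite(self.t_ref)):
            raise ValueError("temperatures must be finite")

    @property
    def is_accelerating(self) -> bool:
        return self.t_device >= self.t_ref


@dataclass(frozen=True)
class ArrayRecord:
    """One microelectrode array's outcome in a soak test."""

    label: str
    substrate: str
    days_elapsed: float
    status: str
    failure_mechanism: str = "none"

    def __post_init__(self) -> None:
        if self.status not in ("working", "failed"):
            raise ValueError(f"status must be 'working' or 'failed', got {self.status!r}")
        if self.failure_mechanism not in FAILURE_MECHANISMS:
            raise ValueError(f"unknown failure mechanism {self.failure_mechanism!r}")
        if self.status == "failed" and self.failure_mechanism in ("none", "minor_permeation"):
            raise ValueError("a failed array needs a hard failure mechanism")
        if self.days_elapsed < 0:
            raise ValueError("days_elapsed must be non-negative")


def aging_factor(cond: AgingCondition) -> float:
    """Time-compression factor ``2^((t_device − t_ref)/10)``.

    Exact for temperature differences that are integer multiples of
    10 °C: (87, 37) → 32, (57, 37) → 4, (37, 37) → 1.  Values below 1
    (device colder than reference) are returned as-is.
    """
    return 2.0 ** ((cond.t_device - cond.t_ref) / 10.0)


def _round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def equivalent_lifetime(days_elapsed: float, factor: float) -> dict[str, float]:
    """Equivalent in-vivo lifetime for a soak of ``days_elapsed`` days.

    Returns a dict with ``days`` (= days_elapsed × factor), ``years``
    (raw, days / 365.25) and ``years_rounded`` (half-up, 2 decimals).
    E.g. 30 days at factor 32 → 960 days, 2.63 years.
    """
    if days_elapsed < 0:
        raise ValueError("days_elapsed must be non-negative")
    if factor <= 0:
        raise ValueError("factor must be positive")
    days = days_elapsed * factor
    years = days / DAYS_PER_YEAR
    return {"days": days, "years": years, "years_rounded": _round_half_up(years)}


def build_summary_table(
    records: Sequence[ArrayRecord],
    cond: AgingCondition = AgingCondition(87.0),
) -> pd.DataFrame:
    """Per-array lifetime summary (one row per record, order preserved).

    Columns: label, substrate, final_status, days_elapsed,
    equivalent_years (2 d.p.), failure_mechanism (human-readable).
    """
    records = list(records)
    if not records:
        raise ValueError("no records given")
    f = aging_factor(cond)
    rows = []
    for r in records:
        life = equivalent_lifetime(r.days_elapsed, f)
        rows.append(
            {
                "label": r.label,
                "substrate": r.substrate,
                "final_status": r.status,
                "days_elapsed": r.days_elapsed,
                "equivalent_years": life["years_rounded"],
                "failure_mechanism": _MECHANISM_LABELS[r.failure_mechanism],
            }
        )
    return pd.DataFrame(rows)


def reference_records() -> list[ArrayRecord]:
    """The packaged eight-array soak-test outcome set (4 PET + 4 SU-8)."""
    ref = resources.files("graphel.data").joinpath("aging_records.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return [
        ArrayRecord(
            label=row.label,
            substrate=row.substrate,
            days_elapsed=float(row.days_elapsed),
            status=row.status,
            failure_mechanism=row.failure_mechanism,
        )
        for row in df.itertuples()
    ]
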