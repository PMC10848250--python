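"""Amorphous-density utilities.

An amorphous solid typically packs at about 95% of the crystallographic
density; that rule of thumb gives a quick estimate where no experimental
amorphous density exists, and signed percent errors quantify how estimates
compare with measured values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DensityRecord",
    "amorphous_density_estimate",
    "percent_error",
    "mean_percent_error",
    "read_density_table",
    "write_density_table",
]

CRYSTALLINE_FRACTION = 0.95


@dataclass(frozen=True)
class DensityRecord:
    """One compound's density bookkeeping (g/cm^3)."""

    name: str
    crystallographic_density: float
    predicted_amorphous: float | None = None
    experimental_amorphous: float | None = None

    def __post_init__(self):
        for v in (
            self.crystallographic_density,
            self.predicted_amorphous,
            self.experimental_amorphous,
        ):
            if v is not None and not v > 0:
                raise ValueError("densities must be positive")

    @property
    def estimated_amorphous(self) -> float:
        return amorphous_density_estimate(self.crystallographic_density)


def amorphous_density_estimate(crystal_density: float) -> float:
    """95%-of-crystallographic-density amorphous estimate, g/cm^3."""
    if not crystal_density > 0:
        raise ValueError("crystallographic density must be positive")
    return CRYSTALLINE_FRACTION * crystal_density


def percent_error(predicted: float, actual: float) -> float:
    """Signed percent error 100 * (predicted - actual) / actual."""
    if actual == 0:
        raise ValueError("actual value must be nonzero")
    return 100.0 * (predicted - actual) / actual


def mean_percent_error(predicted, actual) -> float:
    """Plain arithmetic mean of the signed percent errors."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.size == 0:
        raise ValueError("predicted and actual must be matching non-empty arrays")
    return float(np.mean(100.0 * (p - a) / a))


_COLUMNS = [
    "name",
    "crystallographic_density",
    "estimated_amorphous",
    "predicted_amorphous",
    "experimental_amorphous",
]


def read_density_table(path: str | Path) -> list[DensityRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            DensityRecord(
                name=str(row["name"]),
                crystallographic_density=float(row["crystallographic_density"]),
                predicted_amorphous=(
                    None if pd.isna(row.get("predicted_amorphous"))
                    else float(row["predicted_amorphous"])
                ),
                experimental_amorphous=(
                    None if pd.isna(row.get("experimental_amorphous"))
                    else float(row["experimental_amorphous"])
                ),
            )
        )
    return records


def write_density_table(records, path: str | Path) -> Path:
    """Write records with the 95% estimate rounded to 3 decimals for display."""
    rows = []
    for r in records:
        rows.append(
            {
                "name": r.name,
                "crystallographic_density": r.crystallographic_density,
                "estimated_amorphous": round(r.estimated_amorphous, 3),
                "predicted_amorphous": r.predicted_amorphous,
                "experimental_amorphous": r.experimental_amorphous,
            }
        )
    path = Path(path)
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)
    return path
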