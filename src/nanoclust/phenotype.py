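"""Deterministic threshold rules for the non-spatial phenotype readouts.

Neurite outgrowth scoring (PC12 differentiation), sphere counting with a
size floor, normalisation to a vehicle control, and densitometry ratios for
immunoblots.  All operations are pure arithmetic on tidy records; downstream
significance testing (t-test/ANOVA) is deliberately left to standard
statistics libraries on the tables these functions emit.

Threshold conventions follow the assay definitions literally: a cell is
differentiated when its neurite is strictly longer than 1.5 soma diameters;
a sphere is counted when its size is at least (inclusive) 50 um.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellRecord",
    "SphereRecord",
    "BlotRecord",
    "score_neurite",
    "differentiation_percent",
    "count_spheres",
    "normalize_to_control",
    "densitometry_ratios",
    "score_cell_table",
]

NEURITE_THRESHOLD_RATIO = 1.5
SPHERE_MIN_SIZE_UM = 50.0
MIN_CELLS_PER_CONDITION = 100


@dataclass(frozen=True)
class CellRecord:
    cell_id: str
    neurite_length: float  # um
    soma_diameter: float  # um
    gfp_positive: bool = True

    def __post_init__(self) -> None:
        if self.neurite_length < 0 or self.soma_diameter < 0:
            raise ValueError("lengths must be non-negative")


@dataclass(frozen=True)
class SphereRecord:
    well_id: str
    sphere_sizes: tuple = field(default_factory=tuple)  # um
    condition: str = ""

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sphere_sizes):
            raise ValueError("sphere sizes must be non-negative")


@dataclass(frozen=True)
class BlotRecord:
    band_intensity: float = 0.0
    loading_intensity: float = 1.0  # beta-actin
    phospho_intensity: float = 0.0
    total_intensity: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.band_intensity, self.loading_intensity,
                  self.phospho_intensity, self.total_intensity):
            if v < 0:
                raise ValueError("intensities must be non-negative")


def score_neurite(record: CellRecord,
                  threshold_ratio: float = NEURITE_THRESHOLD_RATIO) -> bool:
    """True iff the neurite is strictly longer than threshold_ratio x soma diameter."""
    if record.soma_diameter <= 0:
        raise ValueError("soma diameter must be positive")
    return record.neurite_length > threshold_ratio * record.soma_diameter


def differentiation_percent(records,
                            threshold_ratio: float = NEURITE_THRESHOLD_RATIO) -> float:
    """Percent of GFP-positive cells scored as differentiated.

    Only GFP-positive (i.e. transfected) cells enter the denominator.  Warns
    when fewer than 100 GFP-positive cells are scored, the assay's stated
    minimum per condition.
    """
    gfp = [r for r in records if r.gfp_positive]
    if not gfp:
        raise ValueError("no GFP-positive cells to score")
    if len(gfp) < MIN_CELLS_PER_CONDITION:
        warnings.warn(
            f"only {len(gfp)} GFP-positive cells; assay minimum is "
            f"{MIN_CELLS_PER_CONDITION}", stacklevel=2)
    positive = sum(score_neurite(r, threshold_ratio) for r in gfp)
    return 100.0 * positive / len(gfp)


def count_spheres(record: SphereRecord,
                  min_size: float = SPHERE_MIN_SIZE_UM) -> int:
    """Number of spheres with size >= min_size um (inclusive threshold)."""
    return int(sum(s >= min_size for s in record.sphere_sizes))


def normalize_to_control(treated_count: float, control_count: float) -> float:
    """Treated count as a percentage of the vehicle control (may exceed 100)."""
    if control_count <= 0:
        raise ValueError("control count must be positive")
    return 100.0 * treated_count / control_count


def densitometry_ratios(record: BlotRecord) -> dict:
    """Loading-normalised band level and phospho/total ratio for one blot lane."""
    if record.loading_intensity <= 0:
        raise ValueError("loading (beta-actin) intensity must be positive")
    if record.total_intensity <= 0:
        raise ValueError("total-protein intensity must be positive")
    return {
        "normalized_level": record.band_intensity / record.loading_intensity,
        "phospho_ratio": record.phospho_intensity / record.total_intensity,
    }


def score_cell_table(df: pd.DataFrame,
                     threshold_ratio: float = NEURITE_THRESHOLD_RATIO) -> pd.DataFrame:
    """Vectorised neurite scoring over a tidy cell table.

    Expects columns ``cell_id, neurite_length, soma_diameter`` and optional
    ``gfp_positive`` (default True); returns the table with a boolean
    ``differentiated`` column appended.
    """
    out = df.copy()
    if "gfp_positive" not in out.columns:
        out["gfp_positive"] = True
    if np.any(out["soma_diameter"] <= 0):
        raise ValueError("soma diameters must be positive")
    out["differentiated"] = (
        out["neurite_length"] > threshold_ratio * out["soma_diameter"]
    )
    return out
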