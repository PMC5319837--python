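"""Comparison metrics between observed and predicted spindles.

Orienting deviation (degrees, 0-90) and centering deviation (% of the
cell's major-axis length) score a model prediction against the observed
spindle.  Clone-pattern classification infers oriented cell divisions
(OCD) from the arrangement of four grand-daughter cells, and the timing
metrics quantify cell-cycle lengthening and animal-vegetal mitotic
asynchrony.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    Contour2D,
    InvalidShapeError,
    SpindleAxis,
    axial_difference,
    principal_axes,
)


@dataclass(frozen=True)
class ClonePattern:
    """Arrangement of four grand-daughters after two rounds of division.

    A daughter dividing parallel to its mother (axial difference below the
    threshold) is an oriented cell division (OCD).  Two orthogonal
    divisions give a square of four cells, one OCD gives a T, two OCDs a
    line.
    """

    pattern: str  # square | T | line
    mother_axis: float
    daughter_axes: tuple[float, float]
    n_ocd: int


def orienting_deviation(observed: SpindleAxis, predicted: SpindleAxis) -> float:
    """Acute angle (degrees, 0-90) between observed and predicted axes."""
    return axial_difference(observed.angle, predicted.angle)


def centering_deviation(
    observed: SpindleAxis, predicted: SpindleAxis, contour: Contour2D
) -> float:
    """Distance between spindle centers as % of the major-axis length.

    The normalization by the contour's major-axis length makes the value
    scale-invariant; "centered within 20%" reads as within 20% of the
    cell's long length.
    """
    axes = principal_axes(contour)
    if axes.degenerate:
        raise InvalidShapeError(
            "centering deviation undefined for an isotropic contour"
        )
    d = float(np.linalg.norm(observed.center - predicted.center))
    return 100.0 * d / axes.length_major


def classify_clone_pattern(
    mother_axis: float,
    daughter_axes: tuple[float, float],
    threshold: float = 45.0,
) -> ClonePattern:
    """Classify a 4-cell clone as square / T / line from division axes.

    Each daughter is parallel to the mother (an OCD) when the axial
    difference is below ``threshold`` (default 45 degrees, the midpoint of
    the axial range); 0, 1 or 2 parallel daughters give square, T or line.
    """
    n_ocd = sum(
        1 for d in daughter_axes if axial_difference(d, mother_axis) < threshold
    )
    pattern = {0: "square", 1: "T", 2: "line"}[n_ocd]
    return ClonePattern(
        pattern=pattern,
        mother_axis=float(mother_axis),
        daughter_axes=(float(daughter_axes[0]), float(daughter_axes[1])),
        n_ocd=n_ocd,
    )


def misorientation_incidence(
    flags_by_lineage: Mapping[str, Sequence[bool]],
) -> pd.DataFrame:
    """Percent of misoriented divisions per lineage.

    Input maps each lineage to per-division booleans (True = the division
    axis departs from the invariant-pattern reference axis by more than
    the scoring threshold).  Empty lineages are omitted with a warning.
    Returns a DataFrame with columns (lineage, n, n_misoriented,
    incidence_pct).
    """
    rows = []
    for lineage, flags in flags_by_lineage.items():
        flags = list(flags)
        if not flags:
            warnings.warn(f"lineage {lineage!r} has no divisions; omitted", stacklevel=2)
            continue
        n_mis = int(sum(bool(f) for f in flags))
        rows.append(
            {
                "lineage": lineage,
                "n": len(flags),
                "n_misoriented": n_mis,
                "incidence_pct": 100.0 * n_mis / len(flags),
            }
        )
    return pd.DataFrame(rows, columns=["lineage", "n", "n_misoriented", "incidence_pct"])


def percent_cycle_increase(prev_duration: float, curr_duration: float) -> float:
    """Percent change of cell-cycle duration relative to the previous cycle.

    +20% means the cycle lengthened by a fifth; negative values mean the
    cycle sped up.
    """
    if prev_duration <= 0 or curr_duration <= 0:
        raise ValueError("cycle durations must be positive")
    return 100.0 * (curr_duration - prev_duration) / prev_duration


def asynchrony(
    entry_times_animal: Sequence[float],
    entry_times_vegetal: Sequence[float],
) -> float:
    """Animal-vegetal mitotic-entry asynchrony in minutes.

    dt = mean(animal) - mean(vegetal); positive when the animal hemisphere
    enters mitosis later.
    """
    a = np.asarray(entry_times_animal, dtype=float)
    v = np.asarray(entry_times_vegetal, dtype=float)
    if a.size == 0 or v.size == 0:
        raise ValueError("both hemispheres need at least one entry time")
    return float(a.mean() - v.mean())
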