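"""Plot aggregation and vegetation indices.

Five indices are supported, all built from the 550/570/670/720/800 nm bands:

====================  =============================
NDVI                  (rho800 - rho670) / (rho800 + rho670)
NDRE                  (rho800 - rho720) / (rho800 + rho720)
CI_rededge            rho800 / rho720 - 1
CI_green              rho800 / rho550 - 1
NDGI                  (rho800 - rho570) / (rho800 + rho570)
====================  =============================

Indices are computed from plot-mean reflectance ("index of means"), not as the
mean of per-pixel indices: a single index value per plot is the convention
matched here, and the two orders agree only on uniform plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import REFLECTANCE, STAGE_INDEX, BandStack, Rect, validate_stage

#: index name -> (band centers required, formula over those bands)
VI_DEFINITIONS = {
    "NDVI": ((800, 670), lambda nir, red: (nir - red) / (nir + red)),
    "NDRE": ((800, 720), lambda nir, re: (nir - re) / (nir + re)),
    "CI_rededge": ((800, 720), lambda nir, re: nir / re - 1.0),
    "CI_green": ((800, 550), lambda nir, green: nir / green - 1.0),
    "NDGI": ((800, 570), lambda nir, green: (nir - green) / (nir + green)),
}

VI_NAMES: tuple[str, ...] = tuple(VI_DEFINITIONS)

#: Indices defined as a normalized difference (bounded in (-1, 1) for
#: strictly positive reflectance).
NORMALIZED_DIFFERENCE_INDICES: tuple[str, ...] = ("NDVI", "NDRE", "NDGI")


def compute_vi(reflectance: Mapping[int, float], index: str) -> float:
    """Evaluate one vegetation index from per-band reflectance.

    ``reflectance`` maps nominal band center (nm) to reflectance.  Raises on a
    missing band or a zero denominator.
    """
    if index not in VI_DEFINITIONS:
        raise KeyError(f"unknown index {index!r}; known: {VI_NAMES}")
    bands, formula = VI_DEFINITIONS[index]
    values = []
    for b in bands:
        if b not in reflectance:
            raise KeyError(f"missing band {b} nm required for {index}")
        values.append(float(reflectance[b]))
    if index in NORMALIZED_DIFFERENCE_INDICES:
        if values[0] + values[1] == 0:
            raise ZeroDivisionError(f"undefined index {index}: zero denominator")
    else:
        if values[1] == 0:
            raise ZeroDivisionError(f"undefined index {index}: zero denominator")
    return float(formula(*values))


def aggregate_plot(stack: BandStack, rect: Rect) -> dict[int, float]:
    """Arithmetic mean reflectance per band over a plot rectangle's interior.

    Rectangles are half-open, as everywhere in the package.
    """
    if stack.value_kind != REFLECTANCE:
        raise ValueError("aggregate_plot expects a reflectance stack")
    window = stack.window(rect)
    means = window.reshape(stack.n_bands, -1).mean(axis=1)
    return {c: float(m) for c, m in zip(stack.band_centers, means)}


@dataclass
class PlotRecord:
    """One variety x stage observation: plot-mean reflectance and its indices."""

    variety: str
    stage: str
    reflectance: dict[int, float]
    vis: dict[str, float] = field(default_factory=dict)
    n_pixels: int = 0

    def __post_init__(self) -> None:
        validate_stage(self.stage)
        for v in self.reflectance.values():
            if not np.isfinite(v):
                raise ValueError(f"non-finite reflectance in plot {self.variety}/{self.stage}")

    def compute_indices(self, indices: Sequence[str] = VI_NAMES) -> "PlotRecord":
        self.vis = {name: compute_vi(self.reflectance, name) for name in indices}
        return self


def vi_table(
    records: Iterable[PlotRecord], indices: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Long-format index table: one row per (variety, stage, index).

    Rows are stably sorted by variety, then chronological stage order, then
    index name.  Duplicate (variety, stage) entries with conflicting
    reflectance raise.
    """
    records = list(records)
    if not records:
        raise ValueError("no plot records supplied")
    if indices is None:
        indices = VI_NAMES
    seen: dict[tuple[str, str], dict[int, float]] = {}
    rows = []
    for rec in records:
        key = (rec.variety, rec.stage)
        if key in seen:
            if seen[key] != rec.reflectance:
                raise ValueError(f"conflicting duplicate record for {key}")
            continue
        seen[key] = rec.reflectance
        for name in indices:
            value = rec.vis.get(name)
            if value is None:
                value = compute_vi(rec.reflectance, name)
            rows.append(
                {
                    "variety": rec.variety,
                    "stage": rec.stage,
                    "index": name,
                    "value": value,
                    "n_pixels": rec.n_pixels,
                }
            )
    df = pd.DataFrame(rows, columns=["variety", "stage", "index", "value", "n_pixels"])
    if df.empty:
        return df
    df["_stage_order"] = df["stage"].map(STAGE_INDEX)
    df = df.sort_values(["variety", "_stage_order", "index"], kind="stable")
    return df.drop(columns="_stage_order").reset_index(drop=True)
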