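"""Shared conventions for the whole pipeline.

Pixel coordinates are 0-based and row-major; rectangles are half-open
``[row0, row1) x [col0, col1)``.  Growth stages are always ordered
TS < JS < PIS < BS < FHS < MRS.  The twelve nominal band centers of the
multispectral camera array are fixed; band lookup everywhere is by exact
nominal center, with no nearest-band fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

#: The six phenological sampling stages, in chronological order:
#: tillering, jointing, panicle initiation, booting, full heading, milk ripening.
STAGES: tuple[str, ...] = ("TS", "JS", "PIS", "BS", "FHS", "MRS")
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

VEGETATIVE_STAGES: tuple[str, ...] = ("TS", "JS", "PIS", "BS")
REPRODUCTIVE_STAGES: tuple[str, ...] = ("FHS", "MRS")

#: Nominal band centers (nm) of the 12-camera multispectral array.
BAND_CENTERS: tuple[int, ...] = (490, 520, 550, 570, 670, 680, 700, 720, 800, 850, 900, 950)

#: Known reflectances of the six ground calibration panels.
PANEL_REFLECTANCES: tuple[float, ...] = (0.03, 0.12, 0.24, 0.36, 0.56, 0.80)

DN = "dn"
REFLECTANCE = "reflectance"


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle ``[row0, row1) x [col0, col1)``."""

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError(f"empty rectangle: {self}")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError(f"negative bounds: {self}")

    @property
    def n_pixels(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)

    def within(self, shape: tuple[int, int]) -> bool:
        return self.row1 <= shape[0] and self.col1 <= shape[1]


@dataclass
class BandStack:
    """A multiband raster: one 2-D pixel grid per band, all sharing a shape.

    ``values`` has shape ``(n_bands, n_rows, n_cols)``; ``value_kind`` is
    either raw digital numbers (``"dn"``) or surface ``"reflectance"``.
    """

    values: np.ndarray
    band_centers: tuple[int, ...]
    value_kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("BandStack values must be (bands, rows, cols)")
        self.band_centers = tuple(int(c) for c in self.band_centers)
        if len(self.band_centers) != self.values.shape[0]:
            raise ValueError("band count does not match band_centers")
        if any(b >= a for b, a in zip(self.band_centers, self.band_centers[1:])):
            raise ValueError("band_centers must be strictly increasing")
        if self.value_kind not in (DN, REFLECTANCE):
            raise ValueError(f"value_kind must be '{DN}' or '{REFLECTANCE}'")

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def band_index(self, center: int) -> int:
        try:
            return self.band_centers.index(int(center))
        except ValueError:
            raise KeyError(f"band {center} nm not present; have {self.band_centers}") from None

    def band(self, center: int) -> np.ndarray:
        return self.values[self.band_index(center)]

    def window(self, rect: Rect) -> np.ndarray:
        """Pixels of ``rect`` for every band, shape (bands, h, w)."""
        if not rect.within(self.shape):
            raise ValueError(f"rectangle {rect} outside raster of shape {self.shape}")
        return self.values[:, rect.row0 : rect.row1, rect.col0 : rect.col1]


@dataclass
class LayoutItem:
    """One rectangle of the scene layout: a research plot or a calibration panel."""

    role: str  # "plot" | "panel"
    item_id: str
    rect: Rect
    variety: Optional[str] = None
    stage: Optional[str] = None
    reflectance: Optional[float] = None  # panels only: known target reflectance

    def __post_init__(self) -> None:
        if self.role not in ("plot", "panel"):
            raise ValueError(f"role must be 'plot' or 'panel', got {self.role!r}")


def validate_stage(stage: str) -> str:
    if stage not in STAGE_INDEX:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return stage


def stage_sorted(stages: Sequence[str]) -> list[str]:
    """Sort stage codes chronologically."""
    return sorted(stages, key=lambda s: STAGE_INDEX[validate_stage(s)])
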