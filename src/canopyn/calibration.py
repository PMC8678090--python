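"""Empirical-line radiometric calibration.

A linear sensor model is assumed per band: ``rho = DN * gain + offset``.
The per-band (gain, offset) pair is fitted by ordinary least squares against
ground calibration panels of known reflectance, then applied pixelwise to
convert digital-number rasters to surface reflectance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import DN, REFLECTANCE, BandStack, LayoutItem


@dataclass
class CalibrationPanelSet:
    """Known panel reflectances paired with observed mean DN per band.

    ``known_reflectance`` has shape (n_panels,), ``dn`` has shape
    (n_panels, n_bands).
    """

    known_reflectance: np.ndarray
    dn: np.ndarray
    band_centers: tuple[int, ...]

    def __post_init__(self) -> None:
        self.known_reflectance = np.asarray(self.known_reflectance, dtype=float)
        self.dn = np.atleast_2d(np.asarray(self.dn, dtype=float))
        self.band_centers = tuple(int(c) for c in self.band_centers)
        if self.known_reflectance.ndim != 1:
            raise ValueError("known_reflectance must be 1-D")
        if self.dn.shape != (self.known_reflectance.size, len(self.band_centers)):
            raise ValueError("dn must have shape (n_panels, n_bands)")
        if np.any(self.known_reflectance <= 0) or np.any(self.known_reflectance > 1):
            raise ValueError("known reflectances must lie in (0, 1]")
        if np.unique(self.known_reflectance).size < 2:
            raise ValueError("need >=2 panels with distinct known reflectance")

    @property
    def n_panels(self) -> int:
        return self.known_reflectance.size


@dataclass
class EmpiricalLineModel:
    """Per-band linear DN -> reflectance calibration.

    ``gain`` is in reflectance per DN, ``offset`` in reflectance units;
    ``rmse`` is the residual root-mean-square of the panel fit per band.
    """

    gain: np.ndarray
    offset: np.ndarray
    rmse: np.ndarray
    n_panels: int
    band_centers: tuple[int, ...]

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        self.rmse = np.asarray(self.rmse, dtype=float)
        self.band_centers = tuple(int(c) for c in self.band_centers)
        n = len(self.band_centers)
        if not (self.gain.shape == self.offset.shape == self.rmse.shape == (n,)):
            raise ValueError("gain/offset/rmse must be one value per band")
        if np.any(self.rmse < 0):
            raise ValueError("RMSE must be non-negative")


def fit_empirical_line(panels: CalibrationPanelSet) -> EmpiricalLineModel:
    """Fit per-band (gain, offset) by OLS of known reflectance on panel DN.

    Each band is fitted independently (no cross-band smoothing).  Raises if a
    band's panel DNs are all identical ("degenerate calibration") or if fewer
    than two panels are supplied.
    """
    if panels.n_panels < 2:
        raise ValueError("need at least 2 calibration panels")
    rho = panels.known_reflectance
    n_bands = len(panels.band_centers)
    gain = np.empty(n_bands)
    offset = np.empty(n_bands)
    rmse = np.empty(n_bands)
    for j in range(n_bands):
        dn = panels.dn[:, j]
        if np.ptp(dn) == 0:
            raise ValueError(
                f"degenerate calibration: all panel DNs identical in band "
                f"{panels.band_centers[j]} nm"
            )
        design = np.column_stack([dn, np.ones_like(dn)])
        coef, *_ = np.linalg.lstsq(design, rho, rcond=None)
        gain[j], offset[j] = coef
        resid = rho - design @ coef
        rmse[j] = float(np.sqrt(np.mean(resid**2)))
    return EmpiricalLineModel(
        gain=gain, offset=offset, rmse=rmse,
        n_panels=panels.n_panels, band_centers=panels.band_centers,
    )


def apply_calibration(
    stack: BandStack, model: EmpiricalLineModel, clip: bool = False
) -> BandStack:
    """Convert a DN raster to reflectance: ``rho = DN * gain + offset`` per band.

    No clipping by default, so calibration errors stay visible; with
    ``clip=True`` output is bounded to [0, 1.2].
    """
    if stack.value_kind != DN:
        raise ValueError("apply_calibration expects a DN stack")
    if stack.band_centers != model.band_centers:
        raise ValueError(
            f"band mismatch: stack has {stack.band_centers}, "
            f"model has {model.band_centers}"
        )
    rho = stack.values * model.gain[:, None, None] + model.offset[:, None, None]
    if clip:
        rho = np.clip(rho, 0.0, 1.2)
    return BandStack(values=rho, band_centers=stack.band_centers, value_kind=REFLECTANCE)


def extract_panel_dns(stack: BandStack, layout: Sequence[LayoutItem]) -> CalibrationPanelSet:
    """Mean DN over each panel rectangle's interior pixels, per band.

    Rectangles follow the half-open convention.  Panels must carry their known
    reflectance in the layout.
    """
    if stack.value_kind != DN:
        raise ValueError("extract_panel_dns expects a DN stack")
    panels = [item for item in layout if item.role == "panel"]
    if len(panels) < 2:
        raise ValueError("layout must contain at least 2 panel rectangles")
    rho = []
    dn = []
    for item in panels:
        if item.reflectance is None:
            raise ValueError(f"panel {item.item_id} has no known reflectance")
        window = stack.window(item.rect)  # raises if out of bounds / empty
        rho.append(float(item.reflectance))
        dn.append(window.reshape(stack.n_bands, -1).mean(axis=1))
    return CalibrationPanelSet(
        known_reflectance=np.array(rho),
        dn=np.array(dn),
        band_centers=stack.band_centers,
    )
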