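"""QCT-style trabecular vBMD: elliptical ROI placement, linear HU->mg/cm^3
calibration, and the three-class bone-density grouping.

Class boundaries (mg/cm^3): normal > 120; 80 <= osteopenia <= 120;
osteoporosis < 80.  Non-osteoporosis = {normal, osteopenia}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .phantom import VoxelVolume
from .segmentation import SegmentationResult

__all__ = ["CalibrationModel", "RoiSpec", "BmdClass", "RoiPlacementError",
           "place_roi", "measure_vbmd", "classify_bmd",
           "OSTEOPOROSIS_THRESHOLD", "NORMAL_THRESHOLD"]

OSTEOPOROSIS_THRESHOLD = 80.0   # mg/cm^3, exclusive (< is osteoporosis)
NORMAL_THRESHOLD = 120.0        # mg/cm^3, exclusive (> is normal)

ROI_AREA_MIN = 90.0   # mm^2
ROI_AREA_MAX = 110.0  # mm^2


class RoiPlacementError(ValueError):
    """Trabecular region too small to host a conforming ROI."""


@dataclass(frozen=True)
class CalibrationModel:
    """Linear HU -> vBMD map; identity by default (phantom convention)."""

    slope: float = 1.0      # (mg/cm^3) per HU
    intercept: float = 0.0  # mg/cm^3

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def to_vbmd(self, hu: float) -> float:
        return self.slope * hu + self.intercept

    def to_hu(self, vbmd: float) -> float:
        return (vbmd - self.intercept) / self.slope


@dataclass(frozen=True)
class RoiSpec:
    center: tuple[float, float]     # (row, col) physical mm
    semi_axes: tuple[float, float]  # (row, col) mm
    slice_index: int

    def __post_init__(self) -> None:
        area = self.area_mm2
        if not (ROI_AREA_MIN <= area <= ROI_AREA_MAX):
            raise ValueError(f"ROI area {area:.1f} mm^2 outside "
                             f"[{ROI_AREA_MIN:g}, {ROI_AREA_MAX:g}]")

    @property
    def area_mm2(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]


@dataclass(frozen=True)
class BmdClass:
    label: str
    vbmd: float

    def __post_init__(self) -> None:
        if self.label != _label_for(self.vbmd):
            raise ValueError(f"label {self.label!r} inconsistent with "
                             f"vBMD {self.vbmd:g}")

    @property
    def is_osteoporosis(self) -> bool:
        return self.label == "osteoporosis"


def _label_for(vbmd: float) -> str:
    if vbmd > NORMAL_THRESHOLD:
        return "normal"
    if vbmd >= OSTEOPOROSIS_THRESHOLD:
        return "osteopenia"
    return "osteoporosis"


def classify_bmd(vbmd: float) -> BmdClass:
    """Three-class grouping; both boundary values belong to osteopenia."""
    if not math.isfinite(vbmd):
        raise ValueError("vBMD must be finite")
    return BmdClass(_label_for(vbmd), float(vbmd))


def _ellipse_pixels(shape, center, semi_axes, spacing):
    ny, nx = shape
    dy, dx = spacing
    y = np.arange(ny) * dy - center[0]
    x = np.arange(nx) * dx - center[1]
    return ((x[None, :] / semi_axes[1]) ** 2
            + (y[:, None] / semi_axes[0]) ** 2) <= 1.0


def place_roi(seg: SegmentationResult, volume: VoxelVolume,
              target_area: float = 100.0) -> RoiSpec:
    """Place an elliptical ROI inside the trabecular core of the mid slice.

    Centered at the trabecular centroid with semi-axes proportioned to the
    core's second moments, scaled to ``target_area`` and shrunk until the
    ellipse lies entirely within the trabecular mask.  Fails with
    :class:`RoiPlacementError` if that forces the area below 90 mm^2.
    """
    if not (ROI_AREA_MIN <= target_area <= ROI_AREA_MAX):
        raise ValueError("target_area must be within the 90-110 mm^2 window")
    dz, dy, dx = volume.voxel_spacing
    trab_slices = [k for k in range(seg.trabecular_mask.shape[0])
                   if seg.trabecular_mask[k].any()]
    if not trab_slices:
        raise RoiPlacementError("no trabecular core to place an ROI in")
    k = trab_slices[len(trab_slices) // 2]
    mask = seg.trabecular_mask[k]
    r, c = np.nonzero(mask)
    center = (r.mean() * dy, c.mean() * dx)
    sy = max(float(np.std(r) * dy), dy)
    sx = max(float(np.std(c) * dx), dx)
    ratio = sy / sx  # semi-axis aspect follows the core's spread
    for shrink in np.geomspace(1.0, ROI_AREA_MIN / target_area, 40):
        area = target_area * shrink
        ax = math.sqrt(area / (math.pi * ratio))
        ay = ratio * ax
        inside = _ellipse_pixels(mask.shape, center, (ay, ax), (dy, dx))
        if inside.any() and not (inside & ~mask).any():
            return RoiSpec(center=center, semi_axes=(ay, ax), slice_index=k)
    raise RoiPlacementError(
        f"trabecular core on slice {k} cannot host a {ROI_AREA_MIN:g} mm^2 ROI")


def measure_vbmd(volume: VoxelVolume, roi: RoiSpec,
                 cal: CalibrationModel | None = None) -> float:
    """vBMD = slope * mean(HU inside the ROI) + intercept."""
    if cal is None:
        cal = CalibrationModel()
    nz, ny, nx = volume.hu_grid.shape
    if not 0 <= roi.slice_index < nz:
        raise ValueError("ROI slice outside the grid")
    dz, dy, dx = volume.voxel_spacing
    inside = _ellipse_pixels((ny, nx), roi.center, roi.semi_axes, (dy, dx))
    if not inside.any():
        raise ValueError("ROI covers no voxel centers")
    mean_hu = float(volume.hu_grid[roi.slice_index][inside].mean())
    return cal.to_vbmd(mean_hu)
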