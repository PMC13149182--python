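"""Four-parameter cortical morphometry from a segmentation result.

Per slice, thickness is sampled by casting rays outward from the body
centroid at uniform angles (12 by default); each ray's thickness is the
physical length of the outermost contiguous cortical run it crosses, with
sub-voxel boundary localisation by linear interpolation of the bilinear
mask profile.  The slice thickness is the mean over rays that hit; the
vertebra thickness and area are unweighted means over measurable slices;
volume and density are voxel sums over the whole cortical mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import VoxelVolume
from .segmentation import SegmentationResult

__all__ = [
    "MorphometryConfig",
    "SliceMorphometry",
    "VertebraMorphometry",
    "measure_slice_thickness",
    "measure_vertebra",
    "cohort_measure",
]

_RAY_STEP_FRACTION = 0.125  # sampling step as a fraction of in-plane spacing


@dataclass(frozen=True)
class MorphometryConfig:
    n_rays: int = 12
    ray_start_angle: float = 0.0       # degrees; 0 = +x (anterior by convention)
    min_hits_per_slice: int = 6
    slice_trim: int = 0                # slices dropped at each end of the body
    density_denominator: str = "cortical"  # or "body": see docs

    def __post_init__(self) -> None:
        if self.n_rays < 3:
            raise ValueError("need at least 3 rays")
        if self.min_hits_per_slice < 1:
            raise ValueError("min_hits_per_slice must be >= 1")
        if self.slice_trim < 0:
            raise ValueError("slice_trim must be >= 0")
        if self.density_denominator not in ("cortical", "body"):
            raise ValueError("density_denominator must be 'cortical' or 'body'")

    @property
    def angles_rad(self) -> np.ndarray:
        start = math.radians(self.ray_start_angle)
        return start + np.arange(self.n_rays) * (2.0 * math.pi / self.n_rays)


@dataclass
class SliceMorphometry:
    slice_index: int
    ray_thicknesses: np.ndarray  # mm, NaN where the ray missed
    mean_thickness: float        # mm, NaN if unmeasurable
    cortical_area: float         # mm^2
    n_hits: int
    measurable: bool


@dataclass
class VertebraMorphometry:
    average_density: float    # sum(HU)/volume, in HU per mm^3
    average_thickness: float  # mm
    average_area: float       # mm^2
    total_volume: float       # mm^3
    n_slices_included: int = 0
    qc_flags: tuple = ()

    def as_dict(self) -> dict:
        return {
            "average_density": self.average_density,
            "average_thickness": self.average_thickness,
            "average_area": self.average_area,
            "total_volume": self.total_volume,
            "n_slices_included": self.n_slices_included,
            "qc_flags": ";".join(self.qc_flags),
        }


def _ray_runs(profile: np.ndarray, ts: np.ndarray) -> list[tuple[float, float]]:
    """Contiguous runs where the interpolated mask profile >= 0.5, with the
    0.5-crossings located by linear interpolation between samples."""
    above = profile >= 0.5
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = [0] if above[0] else []
    ends = []
    for e in edges:
        if above[e + 1]:
            starts.append(e + 1)
        else:
            ends.append(e)
    if above[-1]:
        ends.append(len(profile) - 1)
    runs = []
    for s, e in zip(starts, ends):
        if s > 0:
            v0, v1 = profile[s - 1], profile[s]
            t_in = ts[s - 1] + (0.5 - v0) / (v1 - v0) * (ts[s] - ts[s - 1])
        else:
            t_in = ts[0]
        if e < len(profile) - 1:
            v0, v1 = profile[e], profile[e + 1]
            t_out = ts[e] + (v0 - 0.5) / (v0 - v1) * (ts[e + 1] - ts[e])
        else:
            t_out = ts[-1]
        runs.append((float(t_in), float(t_out)))
    return runs


def measure_slice_thickness(cortical_slice_mask: np.ndarray,
                            centroid_mm: tuple[float, float],
                            spacing: tuple[float, float],
                            config: MorphometryConfig | None = None) -> SliceMorphometry:
    """Ray-cast thickness measurement on one slice.

    ``centroid_mm`` is (row, col) in physical mm with the voxel (0, 0)
    center at the origin; ``spacing`` is (row, col) mm.  Rays that cross no
    cortical voxel are recorded as NaN; the slice is unmeasurable when fewer
    than ``min_hits_per_slice`` rays hit.
    """
    if config is None:
        config = MorphometryConfig()
    mask = np.asarray(cortical_slice_mask, dtype=float)
    dy, dx = spacing
    cy, cx = centroid_mm
    ny, nx = mask.shape
    max_radius = math.hypot(ny * dy, nx * dx)
    step = _RAY_STEP_FRACTION * min(dy, dx)
    ts = np.arange(0.0, max_radius, step)

    thicknesses = np.full(config.n_rays, np.nan)
    for i, theta in enumerate(config.angles_rad):
        ry = cy + ts * math.sin(theta)
        rx = cx + ts * math.cos(theta)
        coords = np.vstack([ry / dy, rx / dx])
        profile = ndimage.map_coordinates(mask, coords, order=1,
                                          mode="constant", cval=0.0)
        runs = _ray_runs(profile, ts)
        if runs:
            t_in, t_out = runs[-1]  # outermost run: robust to interior speckle
            thicknesses[i] = t_out - t_in

    n_hits = int(np.isfinite(thicknesses).sum())
    measurable = n_hits >= config.min_hits_per_slice
    mean_t = float(np.nanmean(thicknesses)) if n_hits else float("nan")
    return SliceMorphometry(
        slice_index=-1,
        ray_thicknesses=thicknesses,
        mean_thickness=mean_t if measurable else float("nan"),
        cortical_area=float(cortical_slice_mask.sum()) * dy * dx,
        n_hits=n_hits,
        measurable=measurable,
    )


def measure_vertebra(seg: SegmentationResult, volume: VoxelVolume,
                     config: MorphometryConfig | None = None) -> VertebraMorphometry:
    """Compute the four vertebra-level parameters.

    average_thickness / average_area: unweighted means over measurable
    slices (after ``slice_trim``); total_volume: cortical voxel count times
    voxel volume; average_density: sum of cortical HU divided by that volume
    (or the whole-body volume with ``density_denominator='body'``).
    """
    if config is None:
        config = MorphometryConfig()
    if seg.cortical_mask.shape != volume.hu_grid.shape:
        raise ValueError("segmentation and volume grids differ")
    dz, dy, dx = volume.voxel_spacing
    n_cortical = int(seg.cortical_mask.sum())
    if n_cortical == 0:
        return VertebraMorphometry(float("nan"), float("nan"), float("nan"),
                                   float("nan"), 0, ("no_cortical_voxels",))

    slices = [k for k in range(volume.hu_grid.shape[0])
              if seg.cortical_mask[k].any()]
    if config.slice_trim:
        slices = slices[config.slice_trim:len(slices) - config.slice_trim]

    flags: list[str] = list(seg.qc_flags)
    per_slice: list[SliceMorphometry] = []
    for k in slices:
        sm = measure_slice_thickness(seg.cortical_mask[k], tuple(seg.per_slice_centroid[k]),
                                     (dy, dx), config)
        sm.slice_index = k
        per_slice.append(sm)
        if not sm.measurable:
            flags.append(f"slice_{k}_unmeasurable")

    good = [sm for sm in per_slice if sm.measurable]
    if not good:
        flags.append("no_measurable_slices")
        avg_t = avg_a = float("nan")
    else:
        avg_t = float(np.mean([sm.mean_thickness for sm in good]))
        avg_a = float(np.mean([sm.cortical_area for sm in good]))

    total_volume = n_cortical * volume.voxel_volume_mm3
    hu_sum = float(volume.hu_grid[seg.cortical_mask].sum())
    if config.density_denominator == "body":
        denom = int(seg.body_mask.sum()) * volume.voxel_volume_mm3
    else:
        denom = total_volume
    avg_density = hu_sum / denom

    return VertebraMorphometry(avg_density, avg_t, avg_a, float(total_volume),
                               len(good), tuple(flags))


def cohort_measure(volumes, seg_config=None, morph_config=None) -> pd.DataFrame:
    """Batch driver: segment and measure every volume, isolating failures.

    Returns one row per input volume, order-preserving; failed subjects get
    NaN parameters and the failure recorded in ``qc_flags``.
    """
    from .segmentation import segment_vertebra

    volumes = list(volumes)
    if not volumes:
        raise ValueError("need at least one volume")
    rows = []
    for i, vol in enumerate(volumes):
        rec = {"subject_id": f"P{i + 1:04d}"}
        try:
            seg = segment_vertebra(vol, seg_config)
            morph = measure_vertebra(seg, vol, morph_config)
            rec.update(morph.as_dict())
        except Exception as exc:  # isolate per-subject failures
            rec.update({
                "average_density": float("nan"),
                "average_thickness": float("nan"),
                "average_area": float("nan"),
                "total_volume": float("nan"),
                "n_slices_included": 0,
                "qc_flags": f"failed:{type(exc).__name__}:{exc}",
            })
        rows.append(rec)
    return pd.DataFrame(rows)
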