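"""Threshold/morphology cortical-trabecular segmentation.

A deliberately simple, fully documented surrogate for the proprietary
vertebral segmentation system the reference measurements came from: per
slice, bone = HU above threshold after morphological closing; the body is
the hole-filled bone mask; cortical = bone, trabecular = body minus bone.
The largest 3-D connected component is retained; more than one large
component is rejected (single-vertebra input is an upstream contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology

from .phantom import VoxelVolume

__all__ = ["SegmentationConfig", "SegmentationResult", "MultipleBodiesError",
           "segment_vertebra"]


class MultipleBodiesError(ValueError):
    """Raised when more than one large bone component is present."""

    def __init__(self, sizes):
        self.component_sizes = tuple(int(s) for s in sizes)
        super().__init__(
            f"expected a single vertebral body, found {len(self.component_sizes)} "
            f"large components with voxel counts {self.component_sizes}")


@dataclass(frozen=True)
class SegmentationConfig:
    bone_threshold: float = 250.0       # HU
    closing_radius: int = 1             # in-plane voxels
    min_component_voxels: int = 64
    slice_range: tuple[int, int] | None = None  # half-open [start, stop)

    def __post_init__(self) -> None:
        if not np.isfinite(self.bone_threshold):
            raise ValueError("bone_threshold must be finite")
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")


@dataclass
class SegmentationResult:
    cortical_mask: np.ndarray
    trabecular_mask: np.ndarray
    body_mask: np.ndarray
    per_slice_centroid: np.ndarray  # (nz, 2) physical mm (row, col); NaN if empty
    qc_flags: tuple = ()

    def __post_init__(self) -> None:
        if np.logical_and(self.cortical_mask, self.trabecular_mask).any():
            raise ValueError("cortical and trabecular masks must be disjoint")
        if np.logical_and(self.cortical_mask, ~self.body_mask).any():
            raise ValueError("cortical mask must be inside the body mask")
        if np.logical_and(self.trabecular_mask, ~self.body_mask).any():
            raise ValueError("trabecular mask must be inside the body mask")

    @property
    def is_empty(self) -> bool:
        return not self.body_mask.any()


def _empty_result(shape, flags) -> SegmentationResult:
    zeros = np.zeros(shape, dtype=bool)
    centroids = np.full((shape[0], 2), np.nan)
    return SegmentationResult(zeros, zeros.copy(), zeros.copy(), centroids,
                              qc_flags=tuple(flags))


def segment_vertebra(volume: VoxelVolume,
                     config: SegmentationConfig | None = None) -> SegmentationResult:
    """Segment a single vertebral body into cortical and trabecular masks.

    Empty bone masks produce a flagged empty result rather than an
    exception; multiple large components raise :class:`MultipleBodiesError`.
    """
    if config is None:
        config = SegmentationConfig()
    hu = volume.hu_grid
    dz, dy, dx = volume.voxel_spacing

    bone = hu >= config.bone_threshold
    if config.slice_range is not None:
        keep = np.zeros(bone.shape[0], dtype=bool)
        keep[slice(*config.slice_range)] = True
        bone[~keep] = False
    if not bone.any():
        return _empty_result(hu.shape, ["no_bone_found"])

    if config.closing_radius > 0:
        footprint = morphology.disk(config.closing_radius)
        for k in range(bone.shape[0]):
            if bone[k].any():
                bone[k] = morphology.closing(bone[k], footprint)

    labels, n_comp = ndimage.label(bone)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
    large = np.flatnonzero(sizes >= config.min_component_voxels) + 1
    flags: list[str] = []
    if large.size > 1:
        raise MultipleBodiesError(sorted(sizes[large - 1], reverse=True))
    if large.size == 0:
        # only speckle above threshold; keep the biggest blob but flag it
        large = np.array([int(np.argmax(sizes)) + 1])
        flags.append("largest_component_below_min_size")
    bone = labels == large[0]

    # slice-wise hole fill matches the slice-wise measurement logic downstream
    body = np.zeros_like(bone)
    for k in range(bone.shape[0]):
        if bone[k].any():
            body[k] = ndimage.binary_fill_holes(bone[k])
    cortical = bone
    trabecular = body & ~cortical
    if not trabecular.any():
        flags.append("no_trabecular_core")

    centroids = np.full((hu.shape[0], 2), np.nan)
    for k in range(hu.shape[0]):
        if body[k].any():
            r, c = np.nonzero(body[k])
            centroids[k] = (r.mean() * dy, c.mean() * dx)

    return SegmentationResult(cortical, trabecular, body, centroids,
                              qc_flags=tuple(flags))
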