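"""CSF-space morphometry: skeleton subdivision and regional width statistics.

The CSF mask (after subtraction of the venous-sinus object) is reduced to
its medial skeleton; each skeleton voxel is tagged by its depth below the
outer surface of the total (skull-peeled) head mask and split into the
subarachnoid-space (SAS) skeleton (depth <= 6 mm, the published 95th
percentile of SAS width) and the sulcal skeleton (deeper).  Local widths
are read off the CSF Euclidean distance transform at skeleton voxels,
calibrated as ``2*(edt - spacing/2)`` so that a slab of odd voxel
thickness is recovered exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .imaging import DistanceMap, Skeleton, VoxelVolume

__all__ = [
    "RegionWidthStats",
    "subtract_vessels",
    "subdivide_skeleton",
    "width_map",
    "roi_extrude",
    "region_width_stats",
]

log = logging.getLogger(__name__)

DEFAULT_DEPTH_THRESHOLD_MM = 6.0


@dataclass
class RegionWidthStats:
    region: str
    mean_width_mm: float
    max_width_mm: float
    n_skeleton_voxels: int

    def __post_init__(self) -> None:
        if self.n_skeleton_voxels >= 1 and not (
            0.0 <= self.mean_width_mm <= self.max_width_mm + 1e-9
        ):
            raise ValueError("inconsistent width statistics (mean > max)")


def subtract_vessels(csf_mask: VoxelVolume, vessel_mask: VoxelVolume) -> VoxelVolume:
    """Remove the segmented vessel object from the CSF object (set difference)."""
    if not csf_mask.same_grid(vessel_mask):
        raise ValueError(
            f"grid mismatch: csf {csf_mask.shape}/{csf_mask.spacing_mm} vs "
            f"vessels {vessel_mask.shape}/{vessel_mask.spacing_mm}"
        )
    out = (csf_mask.values > 0) & ~(vessel_mask.values > 0)
    if not out.any():
        log.warning("vessel subtraction removed every CSF voxel")
    return VoxelVolume(out.astype(np.uint8), csf_mask.spacing_mm, csf_mask.affine)


def subdivide_skeleton(
    csf_skeleton: Skeleton,
    outer_dist: DistanceMap,
    depth_threshold_mm: float = DEFAULT_DEPTH_THRESHOLD_MM,
) -> tuple[Skeleton, Skeleton]:
    """Split the CSF skeleton into SAS (depth <= threshold) and sulcal parts.

    Depth is the outer-surface distance of the total head mask sampled at
    each skeleton voxel; the threshold boundary itself is classified SAS.
    The two parts partition the skeleton exactly.
    """
    if depth_threshold_mm <= 0:
        raise ValueError(f"depth threshold must be > 0, got {depth_threshold_mm}")
    depths = outer_dist.values[tuple(csf_skeleton.coords.T)]
    csf_skeleton.outer_depth_mm = np.asarray(depths, dtype=float)
    is_sas = depths <= depth_threshold_mm
    csf_skeleton.compartment = np.where(is_sas, "sas", "sulcal")
    return csf_skeleton.subset(is_sas), csf_skeleton.subset(~is_sas)


def width_map(skeleton: Skeleton, csf_edt: DistanceMap) -> Skeleton:
    """Fill per-voxel local widths: ``2*edt - spacing/2`` in mm.

    The EDT measures centre-to-centre distance and so overestimates the
    continuous half-thickness by up to half a voxel per side when the
    nearest background lies along a grid axis, but by roughly nothing when
    it lies diagonally (curved or oblique interfaces).  Subtracting a
    quarter voxel per side splits the difference, bounding the error by
    about half a voxel on both flat slabs and curved shells, where a
    full-voxel correction under-reads oblique sheets by more than a voxel.
    Widths are floored at one voxel (a skeleton voxel is at least one
    voxel wide).
    """
    d = csf_edt.values[tuple(skeleton.coords.T)]
    if np.any(d <= 0):
        raise ValueError(
            "skeleton voxel with zero distance-transform value: the skeleton "
            "is not inside the object the EDT was computed on"
        )
    mean_sp = float(np.mean(skeleton.spacing_mm))
    skeleton.width_mm = np.maximum(2.0 * d - 0.5 * mean_sp, mean_sp)
    return skeleton


def roi_extrude(axial_roi: np.ndarray, z_start: int, z_stop: int,
                grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Extrude a 2D axial ROI along z into a 3D mask over slices
    ``[z_start, z_stop)`` (how the frontal-SAS ROI is built from a single
    manually drawn slice)."""
    roi2d = np.asarray(axial_roi) > 0
    if roi2d.shape != grid_shape[:2]:
        raise ValueError(
            f"axial ROI shape {roi2d.shape} does not match in-plane grid {grid_shape[:2]}"
        )
    if not roi2d.any():
        raise ValueError("empty axial ROI")
    if not (0 <= z_start < z_stop <= grid_shape[2]):
        raise ValueError(f"z range [{z_start}, {z_stop}) outside grid of depth {grid_shape[2]}")
    out = np.zeros(grid_shape, dtype=bool)
    out[:, :, z_start:z_stop] = roi2d[:, :, None]
    return out


def region_width_stats(skeleton: Skeleton, roi: np.ndarray, name: str) -> RegionWidthStats:
    """Mean/max local width over skeleton voxels inside the ROI mask."""
    if skeleton.width_mm is None:
        raise ValueError("skeleton has no width attribute; run width_map first")
    roi = np.asarray(roi) > 0
    inside = roi[tuple(skeleton.coords.T)] if len(skeleton) else np.zeros(0, bool)
    if not inside.any():
        return RegionWidthStats(name, float("nan"), float("nan"), 0)
    w = skeleton.width_mm[inside]
    return RegionWidthStats(name, float(w.mean()), float(w.max()), int(inside.sum()))
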