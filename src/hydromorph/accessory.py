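"""Accessory segmentation and volumetry: seed-based region growing
(Meckel's cave), mask volumetry, and the lateral-ventricle
anterior/posterior split.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .imaging import VoxelVolume, _STRUCT_26

__all__ = ["region_grow", "mask_volume", "split_lv"]


def region_grow(image: VoxelVolume, seeds, tolerance: float) -> VoxelVolume:
    """Grow a 26-connected region from seed voxels by intensity similarity.

    A voxel joins the region iff it is 26-connected to a seed through
    voxels whose intensity differs from the *seed-mean* by at most
    ``tolerance``.  The reference intensity is fixed at the seed mean (not
    updated during growth), which makes the result deterministic and
    independent of visiting order; seeds are always included.
    """
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    seeds = np.atleast_2d(np.asarray(seeds, dtype=int))
    shape = np.asarray(image.shape)
    if seeds.shape[1] != 3 or ((seeds < 0) | (seeds >= shape)).any():
        raise ValueError(f"seed outside the {tuple(shape)} grid: {seeds.tolist()}")
    ref = float(np.mean(image.values[tuple(seeds.T)]))
    similar = np.abs(image.values - ref) <= tolerance
    similar[tuple(seeds.T)] = True  # seeds always belong to the object
    labels, _ = ndimage.label(similar, structure=_STRUCT_26)
    seed_labels = np.unique(labels[tuple(seeds.T)])
    grown = np.isin(labels, seed_labels[seed_labels > 0])
    return VoxelVolume(grown.astype(np.uint8), image.spacing_mm, image.affine)


def mask_volume(mask: VoxelVolume) -> float:
    """Volume of a binary mask in mm^3 (voxel count x voxel volume)."""
    return float(np.count_nonzero(mask.values)) * mask.voxel_volume_mm3


def split_lv(lv_mask: VoxelVolume, axis: int = 2) -> tuple[float, float]:
    """Split a lateral-ventricle mask into anterior/posterior compartments
    at the midpoint of its bounding extent along ``axis`` and return both
    compartment volumes (mm^3).  A slice lying exactly on the midpoint
    plane is shared half-half; the two volumes always sum to the total.
    """
    m = lv_mask.values > 0
    if not m.any():
        raise ValueError("empty lateral-ventricle mask")
    coord = np.nonzero(m)[axis]
    mid = (coord.min() + coord.max()) / 2.0
    below = int(np.count_nonzero(coord < mid))
    above = int(np.count_nonzero(coord > mid))
    tie = int(m.sum()) - below - above  # slice exactly on the split plane
    vv = lv_mask.voxel_volume_mm3
    return (below + tie / 2.0) * vv, (above + tie / 2.0) * vv
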