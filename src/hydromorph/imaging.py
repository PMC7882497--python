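"""Geometry primitives shared by all imaging stages.

Volumes are plain 3D numpy grids with millimetre voxel spacing carried
alongside (the NIfTI convention: 0-based voxel indices, coordinates in mm
are voxel-centre positions under the volume affine).  All distances
reported anywhere in the package are physical (mm), never voxel counts:
the Euclidean distance transform and all path lengths are spacing-aware.

The medial representation used throughout is a one-voxel-thick skeleton
with 26-neighbourhood adjacency; diagonal steps are weighted by the
physical step length (``sqrt(dx**2 + dy**2 + dz**2)`` in mm).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelVolume",
    "DistanceMap",
    "Skeleton",
    "CenterlinePath",
    "read_volume",
    "write_volume",
    "edt",
    "outer_surface_distance",
    "skeletonize",
    "skeleton_from_mask",
    "longest_path",
    "connected_components",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VoxelVolume:
    """A 3D scalar grid with physical voxel spacing in mm.

    Parameters
    ----------
    values
        3D array of voxel values.
    spacing_mm
        Per-axis voxel size in mm, strictly positive.
    affine
        Optional 4x4 voxel-to-world matrix; preserved verbatim on write.
        When absent, a diagonal affine built from the spacing is used.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"volume must be 3D, got shape {self.values.shape}"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def astype_mask(self) -> "VoxelVolume":
        """View the volume as a binary mask (values coerced to {0,1})."""
        return VoxelVolume((self.values > 0).astype(np.uint8), self.spacing_mm, self.affine)

    def same_grid(self, other: "VoxelVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing_mm, other.spacing_mm)


@dataclass
class DistanceMap(VoxelVolume):
    """Per-voxel distance in mm; the ``mode`` field records the reference
    surface: ``"background"`` (within-object distance to nearest background
    voxel centre) or ``"outer_surface"`` (depth below the outermost edge of
    the total head mask)."""

    mode: str = "background"


@dataclass
class Skeleton:
    """One-voxel-thick medial representation of a binary mask.

    ``coords`` is an (n, 3) integer array of skeleton voxel positions;
    per-voxel attributes (local width in mm, outer-surface depth in mm,
    compartment tag) are parallel arrays filled by downstream stages.
    """

    coords: np.ndarray
    spacing_mm: tuple[float, float, float]
    shape: tuple[int, int, int]
    width_mm: np.ndarray | None = None
    outer_depth_mm: np.ndarray | None = None
    compartment: np.ndarray | None = None  # per-voxel tag, e.g. "sas"/"sulcal"

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.int64))

    def __len__(self) -> int:
        return 0 if self.coords.size == 0 else self.coords.shape[0]

    def as_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        if len(self):
            m[tuple(self.coords.T)] = True
        return m

    def subset(self, keep: np.ndarray) -> "Skeleton":
        """Return a skeleton restricted to the boolean/index selection ``keep``."""
        return Skeleton(
            self.coords[keep],
            self.spacing_mm,
            self.shape,
            None if self.width_mm is None else self.width_mm[keep],
            None if self.outer_depth_mm is None else self.outer_depth_mm[keep],
            None if self.compartment is None else self.compartment[keep],
        )

    def graph(self) -> nx.Graph:
        """26-connectivity adjacency graph; edges weighted by physical step length."""
        g = nx.Graph()
        sp = np.asarray(self.spacing_mm)
        nodes = [tuple(c) for c in self.coords]
        g.add_nodes_from(nodes)
        index = set(nodes)
        offsets = [
            (i, j, k)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) > (0, 0, 0)
        ]
        for c in nodes:
            for off in offsets:
                nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
                if nb in index:
                    w = float(np.sqrt(np.sum((np.asarray(off) * sp) ** 2)))
                    g.add_edge(c, nb, weight=w)
        return g


@dataclass
class CenterlinePath:
    """Ordered voxel path along a skeleton; consecutive points are 26-neighbours."""

    coords: np.ndarray
    spacing_mm: tuple[float, float, float]
    cumulative_mm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.int64))
        sp = np.asarray(self.spacing_mm)
        if self.coords.shape[0] > 1:
            steps = np.sqrt(((np.diff(self.coords, axis=0) * sp) ** 2).sum(axis=1))
            self.cumulative_mm = np.concatenate([[0.0], np.cumsum(steps)])
        else:
            self.cumulative_mm = np.zeros(self.coords.shape[0] or 1)

    @property
    def arc_length_mm(self) -> float:
        return float(self.cumulative_mm[-1])

    @property
    def chord_length_mm(self) -> float:
        sp = np.asarray(self.spacing_mm)
        return float(np.sqrt((((self.coords[-1] - self.coords[0]) * sp) ** 2).sum()))


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a NIfTI-1 volume (.nii or .nii.gz); must be 3D."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise ValueError(f"not a readable NIfTI file: {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape} in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelVolume(data, spacing, np.asarray(img.affine))


def write_volume(vol: VoxelVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1; orientation metadata preserved verbatim."""
    if np.issubdtype(vol.values.dtype, np.floating) and not np.all(np.isfinite(vol.values)):
        raise ValueError("refusing to write non-finite voxel values")
    affine = vol.affine
    if affine is None:
        affine = np.diag(list(vol.spacing_mm) + [1.0])
    img = nib.Nifti1Image(vol.values, affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))
    return Path(path)


# ---------------------------------------------------------------------------
# Distance transforms


def edt(mask: VoxelVolume) -> DistanceMap:
    """Spacing-aware Euclidean distance transform of a binary mask.

    Each object voxel gets the mm distance from its centre to the nearest
    background voxel centre; background voxels get 0.
    """
    m = mask.values > 0
    if not m.any():
        raise ValueError("empty mask has no distance transform")
    if m.all():
        raise ValueError("mask has no background voxel; distances undefined")
    d = ndimage.distance_transform_edt(m, sampling=mask.spacing_mm)
    return DistanceMap(d, mask.spacing_mm, mask.affine, mode="background")


def outer_surface_distance(total_mask: VoxelVolume) -> DistanceMap:
    """Depth of each voxel below the outermost edge of the total (skull-peeled)
    head mask — definitionally the EDT of the total mask itself."""
    d = edt(total_mask)
    return DistanceMap(d.values, d.spacing_mm, d.affine, mode="outer_surface")


# ---------------------------------------------------------------------------
# Skeletonization


def connected_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """26-connected labelling of a boolean grid."""
    return ndimage.label(mask, structure=_STRUCT_26)


# --- simple-point machinery for the thinning ------------------------------
# A voxel is "simple" (deletable without changing topology) iff its 3x3x3
# neighbourhood has exactly one 26-connected object component among the 26
# neighbours and exactly one 6-connected background component within the
# 18-neighbourhood that is 6-adjacent to the centre.  Checks are memoized on
# the packed 26-bit neighbourhood configuration.

_N26_OFFSETS = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]
_N6_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
_N18_IDX = [
    n for n, off in enumerate(_N26_OFFSETS) if sum(abs(v) for v in off) <= 2
]
_N6_IDX = [n for n, off in enumerate(_N26_OFFSETS) if sum(abs(v) for v in off) == 1]

# adjacency among the 26 neighbour positions
_ADJ26 = [
    [
        m
        for m, o2 in enumerate(_N26_OFFSETS)
        if m != n and max(abs(o2[0] - o1[0]), abs(o2[1] - o1[1]), abs(o2[2] - o1[2])) <= 1
    ]
    for n, o1 in enumerate(_N26_OFFSETS)
]
# 6-adjacency among the 18-neighbourhood positions
_ADJ6_18 = [
    [
        m
        for m in _N18_IDX
        if m != n
        and sum(abs(a - b) for a, b in zip(_N26_OFFSETS[m], _N26_OFFSETS[n])) == 1
    ]
    for n in range(26)
]

_simple_cache: dict[int, bool] = {}


def _is_simple(bits: int) -> bool:
    cached = _simple_cache.get(bits)
    if cached is not None:
        return cached
    occ = [(bits >> n) & 1 for n in range(26)]
    # one 26-connected object component among the neighbours
    seen = [False] * 26
    ncomp = 0
    for n in range(26):
        if occ[n] and not seen[n]:
            ncomp += 1
            if ncomp > 1:
                break
            stack = [n]
            seen[n] = True
            while stack:
                u = stack.pop()
                for v in _ADJ26[u]:
                    if occ[v] and not seen[v]:
                        seen[v] = True
                        stack.append(v)
    ok = ncomp == 1
    if ok:
        # one 6-connected background component in N18 touching the centre
        seen = [False] * 26
        ncomp = 0
        for n in _N6_IDX:
            if not occ[n] and not seen[n]:
                ncomp += 1
                if ncomp > 1:
                    break
                stack = [n]
                seen[n] = True
                while stack:
                    u = stack.pop()
                    for v in _ADJ6_18[u]:
                        if not occ[v] and not seen[v]:
                            seen[v] = True
                            stack.append(v)
        ok = ncomp == 1
    _simple_cache[bits] = ok
    return ok


_POW2 = (2 ** np.arange(26)).astype(np.int64)


def _ridge_anchors(m: np.ndarray, spacing) -> np.ndarray:
    """Medial anchors: voxels whose distance-transform value equals the
    maximum over their 26-neighbourhood (flat medial plateaus are anchored
    whole, so sheet-like medial surfaces survive thinning)."""
    d = ndimage.distance_transform_edt(m, sampling=spacing)
    plateau_max = d >= ndimage.maximum_filter(d, size=3)
    # require a strict descent across the structure along some axis whose
    # both neighbours are object voxels: this anchors the medial layer(s)
    # of slabs, shells and odd tubes but not flat boundary plateaus (e.g.
    # a 2x2 bar, which should thin to a line)
    strict = np.zeros_like(m)
    for ax in range(3):
        dp, dm_ = np.roll(d, -1, ax), np.roll(d, 1, ax)
        op, om = np.roll(m, -1, ax), np.roll(m, 1, ax)
        # zero the wrapped faces
        sl = [slice(None)] * 3
        sl[ax] = -1
        dp[tuple(sl)] = 0; op[tuple(sl)] = False
        sl[ax] = 0
        dm_[tuple(sl)] = 0; om[tuple(sl)] = False
        strict |= op & om & (d > np.minimum(dp, dm_))
    return m & plateau_max & strict


def skeletonize(mask: VoxelVolume) -> Skeleton:
    """Topology-preserving 3D thinning of a binary mask.

    Simple points are deleted sequentially (fixed scan order, so the result
    is deterministic) until stable, protecting curve endpoints and the EDT
    ridge anchors; sheet-like compartments (fissures, the CSF shell) thus
    retain their medial surface instead of eroding away, while tubes and
    slabs thin to their medial curve/plane.  The skeleton is one voxel
    thick transverse to each local medial structure and preserves the
    26-connected component count of the input exactly.
    """
    m = mask.values > 0
    if not m.any():
        raise ValueError("cannot skeletonize an empty mask")
    work = np.pad(m, 1)  # guard border so neighbourhoods never clip
    anchors = np.pad(_ridge_anchors(m, mask.spacing_mm), 1)
    dist = np.pad(ndimage.distance_transform_edt(m, sampling=mask.spacing_mm), 1)
    while True:
        # border voxels: object with a 6-connected background neighbour,
        # processed in increasing distance-to-background order so erosion
        # proceeds from the surface inward (distance-ordered homotopic
        # thinning; near-equivariant under grid rotations)
        eroded = ndimage.binary_erosion(work, ndimage.generate_binary_structure(3, 1))
        cand = np.argwhere(work & ~eroded & ~anchors)
        if len(cand):
            order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0],
                                dist[tuple(cand.T)]))
            cand = cand[order]
        deleted = 0
        for x, y, z in cand:
            if not work[x, y, z]:
                continue
            nb = work[x - 1:x + 2, y - 1:y + 2, z - 1:z + 2].ravel()
            nb = np.delete(nb, 13)
            n_obj = int(nb.sum())
            if n_obj <= 1:  # isolated voxel or curve endpoint
                continue
            bits = int(nb @ _POW2)
            if _is_simple(bits):
                work[x, y, z] = False
                deleted += 1
        if deleted == 0:
            break
    sk = work[1:-1, 1:-1, 1:-1]
    return Skeleton(np.argwhere(sk), mask.spacing_mm, m.shape)


def skeleton_from_mask(mask_array: np.ndarray, spacing_mm=(1.0, 1.0, 1.0)) -> Skeleton:
    """Wrap an already-thin boolean array as a Skeleton (no thinning)."""
    return Skeleton(np.argwhere(mask_array > 0), tuple(spacing_mm), mask_array.shape)


# ---------------------------------------------------------------------------
# Longest path


def _dijkstra(adj: dict, source, spacing: np.ndarray) -> dict:
    """Weighted shortest-path lengths + predecessors from one source."""
    dist = {source: 0.0}
    pred = {source: None}
    pq = [(0.0, source)]
    while pq:
        d, u = heapq.heappop(pq)
        if d > dist.get(u, np.inf):
            continue
        for v, w in adj[u]:
            nd = d + w
            if nd < dist.get(v, np.inf) - 1e-12:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(pq, (nd, v))
    return dist, pred


def _build_adj(coords: np.ndarray, spacing: np.ndarray) -> dict:
    nodes = [tuple(c) for c in coords]
    index = set(nodes)
    adj = {c: [] for c in nodes}
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    wcache = {
        off: float(np.sqrt(np.sum((np.asarray(off) * spacing) ** 2))) for off in offsets
    }
    for c in nodes:
        for off in offsets:
            nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            if nb in index:
                adj[c].append((nb, wcache[off]))
    return adj


def longest_path(skeleton: Skeleton) -> CenterlinePath:
    """Maximum-arc-length geodesic between two endpoint voxels of a connected
    skeleton component.

    Endpoints are degree-1 voxels under 26-connectivity; for a component
    without endpoints (a cycle) the longest shortest path over all voxel
    pairs is returned.  Ties are broken by the lexicographically smallest
    endpoint pair, so the result is deterministic.
    """
    if len(skeleton) == 0:
        raise ValueError("empty skeleton component")
    coords = skeleton.coords
    sp = np.asarray(skeleton.spacing_mm)
    if coords.shape[0] == 1:
        return CenterlinePath(coords, skeleton.spacing_mm)
    adj = _build_adj(coords, sp)
    endpoints = sorted(c for c, nbrs in adj.items() if len(nbrs) == 1)
    # cycles (or a lone endpoint) have no usable endpoint pair: fall back to
    # the longest shortest path over all voxel pairs
    nodes = endpoints if len(endpoints) >= 2 else sorted(adj)
    best = None  # (arc length, sorted endpoint pair, pred map, dst)
    for src in nodes:
        dist, pred = _dijkstra(adj, src, sp)
        if len(dist) < len(adj):
            raise ValueError("skeleton component is not connected")
        for dst in nodes:
            if dst == src:
                continue
            d = dist[dst]
            pair = tuple(sorted((src, dst)))
            if (best is None or d > best[0] + 1e-9
                    or (abs(d - best[0]) <= 1e-9 and pair < best[1])):
                best = (d, pair, pred, dst)
    _, _, pred, dst = best
    path = [dst]
    while pred[path[-1]] is not None:
        path.append(pred[path[-1]])
    path.reverse()
    # orient from the lexicographically smaller endpoint
    if path[0] > path[-1]:
        path.reverse()
    return CenterlinePath(np.asarray(path), skeleton.spacing_mm)
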