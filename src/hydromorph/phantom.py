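"""Synthetic 3D head phantoms with exactly known geometry.

The phantom emulates the anatomy the morphometry pipeline quantifies on
T2-weighted-like infant scans (CSF bright, tissue dark): a brain
ellipsoid wrapped in a CSF shell whose frontal sector is thickened to a
controlled subarachnoid-space (SAS) width, a midline interhemispheric-
fissure (IHF) slab, sulcal invaginations, two optic-nerve tubes with a
planar sinusoidal centerline of controlled amplitude/wavelength, a pair
of Meckel's-cave blobs and a venous-sinus tube riding on the posterior
shell.  Every structure's continuous-geometry ground truth (widths, arc
lengths, arch-to-chord ratios, volumes) is returned alongside the
voxelized volumes, so downstream measurements have an analytic
acceptance surface.

The CSF shell is built as a constant-thickness offset band of the brain
surface (voxels whose distance to the brain is in ``(0, t]``), so its
local width is the requested thickness everywhere except at the
frontal/posterior transition, which the emitted ROI masks exclude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging import VoxelVolume, write_volume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "LABELS",
    "make_head_phantom",
    "make_tube_mask",
    "sinusoid_centerline",
    "sinusoid_arc_length",
]

# label legend: id -> structure
LABELS = {
    0: "background",
    1: "brain",
    2: "sas_shell",
    3: "frontal_sas",
    4: "ihf",
    5: "sulcus",
    6: "on_left",
    7: "on_right",
    8: "meckel_left",
    9: "meckel_right",
    10: "venous_sinus",
}

CSF_LIKE_LABELS = (2, 3, 4, 5, 8, 9, 10)


@dataclass
class PhantomSpec:
    """Generative parameters of a head phantom; all lengths in mm."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_semiaxes_mm: tuple[float, float, float] = (30.0, 34.0, 27.0)
    base_sas_thickness_mm: float = 2.0
    frontal_sas_thickness_mm: float = 4.0
    ihf_width_mm: float = 3.0
    n_sulci: int = 3
    sulcus_width_mm: float = 3.0
    sulcus_depth_mm: float = 10.0
    # optic nerves: (left, right) tuples
    on_radius_mm: tuple[float, float] = (2.0, 2.0)
    on_length_mm: tuple[float, float] = (22.0, 22.0)  # chord (axis) extent
    on_sine_amplitude_mm: tuple[float, float] = (1.5, 1.5)
    on_sine_wavelength_mm: tuple[float, float] = (11.0, 11.0)
    meckel_radius_mm: tuple[float, float] = (3.0, 3.0)
    sinus_radius_mm: float = 2.5
    csf_high: float = 100.0
    tissue_low: float = 40.0
    background: float = 5.0
    noise_sd: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        def _nonneg(name):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if (v < 0).any():
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

        for name in (
            "base_sas_thickness_mm", "frontal_sas_thickness_mm", "ihf_width_mm",
            "n_sulci", "sulcus_width_mm", "sulcus_depth_mm", "on_radius_mm",
            "on_length_mm", "on_sine_amplitude_mm", "on_sine_wavelength_mm",
            "meckel_radius_mm", "sinus_radius_mm", "noise_sd", "brain_semiaxes_mm",
        ):
            _nonneg(name)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        lim = 0.25 * min(self.brain_semiaxes_mm)
        if self.frontal_sas_thickness_mm > lim:
            raise ValueError(
                f"frontal_sas_thickness_mm={self.frontal_sas_thickness_mm} exceeds "
                f"0.25*min(brain_semiaxes_mm)={lim}"
            )
        if self.ihf_width_mm > lim:
            raise ValueError(
                f"ihf_width_mm={self.ihf_width_mm} exceeds 0.25*min(brain_semiaxes_mm)={lim}"
            )
        for i in range(2):
            a, wl, r = (self.on_sine_amplitude_mm[i], self.on_sine_wavelength_mm[i],
                        self.on_radius_mm[i])
            # centerline curvature radius (lambda^2 / (4 pi^2 a)) must exceed
            # the tube radius or the tube self-intersects at the bends
            if a > 0 and wl ** 2 < 4 * np.pi ** 2 * a * r:
                raise ValueError(
                    f"on_sine_wavelength_mm[{i}]={wl} too short for amplitude {a} "
                    f"and radius {r}: tube would self-intersect"
                )
        # head (brain + shell) must fit with a >=2-voxel background margin
        shell = max(self.base_sas_thickness_mm, self.frontal_sas_thickness_mm)
        for ax in range(3):
            extent = 2 * (self.brain_semiaxes_mm[ax] + shell) / self.spacing_mm[ax]
            if extent > self.grid_shape[ax] - 4:
                raise ValueError(
                    f"grid_shape axis {ax} too small for brain + shell + 2-voxel margin"
                )


@dataclass
class PhantomTruth:
    """Continuous-geometry ground truth of a generated phantom (no
    voxelization error: values come from the generating parameters)."""

    fsas_mean_mm: float
    fsas_max_mm: float
    ihf_mean_mm: float
    ihf_max_mm: float
    on_arc_length_mm: tuple[float, float]
    on_chord_length_mm: tuple[float, float]
    on_diameter_mm: tuple[float, float]
    on_arch_chord_ratio: tuple[float, float]
    meckel_volume_mm3: tuple[float, float]
    label_legend: dict = field(default_factory=lambda: dict(LABELS))
    roi_frontal: np.ndarray | None = None
    roi_ihf: np.ndarray | None = None
    roi_on: tuple[np.ndarray, np.ndarray] | None = None

    def to_json(self, path: str | Path) -> None:
        d = {k: v for k, v in asdict(self).items()
             if k not in ("roi_frontal", "roi_ihf", "roi_on")}
        d["label_legend"] = {str(k): v for k, v in self.label_legend.items()}
        Path(path).write_text(json.dumps(d, indent=2, default=list))


def sinusoid_arc_length(chord_mm: float, amplitude_mm: float, wavelength_mm: float,
                        n_quad: int = 4096) -> float:
    """Arc length of ``(t, a*sin(2*pi*t/lambda))`` for t in [0, chord], by
    composite quadrature of ``sqrt(1 + (da/dt)^2)``."""
    if amplitude_mm == 0 or chord_mm == 0:
        return float(chord_mm)
    t = np.linspace(0.0, chord_mm, n_quad)
    k = 2 * np.pi / wavelength_mm
    integrand = np.sqrt(1.0 + (amplitude_mm * k * np.cos(k * t)) ** 2)
    return float(np.trapezoid(integrand, t))


def sinusoid_centerline(start_mm: np.ndarray, axis: np.ndarray, deflect: np.ndarray,
                        chord_mm: float, amplitude_mm: float, wavelength_mm: float,
                        step_mm: float = 0.25) -> np.ndarray:
    """Sample points (mm coordinates) of a planar sinusoidal centerline:
    ``start + t*axis + a*sin(2*pi*t/lambda)*deflect`` with unit vectors
    ``axis`` perpendicular to ``deflect``."""
    n = max(int(np.ceil(chord_mm / step_mm)) + 1, 2)
    t = np.linspace(0.0, chord_mm, n)
    k = 2 * np.pi / wavelength_mm if wavelength_mm > 0 else 0.0
    s = amplitude_mm * np.sin(k * t) if amplitude_mm > 0 else np.zeros_like(t)
    return (np.asarray(start_mm)[None, :]
            + t[:, None] * np.asarray(axis)[None, :]
            + s[:, None] * np.asarray(deflect)[None, :])


def make_tube_mask(centerline_mm: np.ndarray, radius_mm: float,
                   grid_shape: tuple[int, int, int],
                   spacing_mm=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Boolean mask of voxels whose centre lies within ``radius_mm`` of the
    polyline through ``centerline_mm`` (exact point-to-segment distance)."""
    pts = np.atleast_2d(np.asarray(centerline_mm, dtype=float))
    if pts.size == 0:
        raise ValueError("empty centerline")
    sp = np.asarray(spacing_mm, dtype=float)
    if radius_mm < sp.min():
        raise ValueError(
            f"tube radius {radius_mm} mm is below the voxel spacing {sp.min()} mm; "
            "the tube would not be reliably voxelized"
        )
    # candidate voxels: bounding box of the curve dilated by the radius
    lo = np.maximum(np.floor((pts.min(axis=0) - radius_mm) / sp - 1), 0).astype(int)
    hi = np.minimum(np.ceil((pts.max(axis=0) + radius_mm) / sp + 1),
                    np.asarray(grid_shape) - 1).astype(int)
    ii, jj, kk = np.meshgrid(*[np.arange(lo[a], hi[a] + 1) for a in range(3)],
                             indexing="ij")
    centers = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * sp  # voxel centres, mm
    dmin = np.full(centers.shape[0], np.inf)
    if pts.shape[0] == 1:
        dmin = np.linalg.norm(centers - pts[0], axis=1)
    else:
        for a, b in zip(pts[:-1], pts[1:]):
            ab = b - a
            denom = float(ab @ ab)
            if denom == 0.0:
                d = np.linalg.norm(centers - a, axis=1)
            else:
                tt = np.clip((centers - a) @ ab / denom, 0.0, 1.0)
                d = np.linalg.norm(centers - a - tt[:, None] * ab, axis=1)
            np.minimum(dmin, d, out=dmin)
    mask = np.zeros(grid_shape, dtype=bool)
    inside = dmin <= radius_mm
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)[inside]
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return mask


def _ellipsoid(shape, spacing, center_mm, semiaxes_mm) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    q = sum(((g - c) / max(a, 1e-9)) ** 2
            for g, c, a in zip(grids, center_mm, semiaxes_mm))
    return q <= 1.0


def make_head_phantom(spec: PhantomSpec):
    """Generate (intensity volume, label volume, truth) for a head phantom.

    Deterministic given ``spec`` (including ``rng_seed``): identical specs
    produce bit-identical volumes.
    """
    spec.validate()
    shape = tuple(spec.grid_shape)
    sp = np.asarray(spec.spacing_mm, dtype=float)
    center = (np.asarray(shape) - 1) / 2.0 * sp  # mm

    labels = np.zeros(shape, dtype=np.uint8)
    brain = _ellipsoid(shape, sp, center, spec.brain_semiaxes_mm)
    labels[brain] = 1

    # CSF shell: constant-thickness offset band of the brain surface
    d_out = ndimage.distance_transform_edt(~brain, sampling=sp)
    ygrid = np.arange(shape[1])[None, :, None] * sp[1]
    frontal_sector = np.broadcast_to(ygrid > center[1], shape)
    if spec.base_sas_thickness_mm > 0:
        shell = (~brain) & (d_out <= spec.base_sas_thickness_mm) & ~frontal_sector
        labels[shell] = 2
    if spec.frontal_sas_thickness_mm > 0:
        fshell = (~brain) & (d_out <= spec.frontal_sas_thickness_mm) & frontal_sector
        labels[fshell] = 3

    # interhemispheric fissure: midline slab carved from the upper brain
    if spec.ihf_width_mm > 0:
        xgrid = np.arange(shape[0])[:, None, None] * sp[0]
        zgrid = np.arange(shape[2])[None, None, :] * sp[2]
        slab = (np.abs(np.broadcast_to(xgrid, shape) - center[0]) <= spec.ihf_width_mm / 2.0)
        slab &= np.broadcast_to(zgrid, shape) > center[2]
        labels[brain & slab] = 4

    # sulci: coronal invaginations of controlled width and depth
    if spec.n_sulci > 0 and spec.sulcus_width_mm > 0 and spec.sulcus_depth_mm > 0:
        d_in = ndimage.distance_transform_edt(brain, sampling=sp)
        zgrid = np.arange(shape[2])[None, None, :] * sp[2]
        upper = np.broadcast_to(zgrid, shape) > center[2]
        ys = np.linspace(center[1] - 0.5 * spec.brain_semiaxes_mm[1],
                         center[1] + 0.5 * spec.brain_semiaxes_mm[1],
                         spec.n_sulci)
        for y0 in ys:
            cut = np.abs(np.broadcast_to(ygrid, shape) - y0) <= spec.sulcus_width_mm / 2.0
            labels[brain & cut & upper & (d_in <= spec.sulcus_depth_mm)
                   & (labels != 4)] = 5

    # optic nerves: sinusoidal tubes in free space anterior-inferior to the head
    on_curves = []
    z0 = 4.0 * sp[2] + max(spec.on_radius_mm)
    for i, (side_sign, lab) in enumerate(((-1, 6), (1, 7))):
        r, L = spec.on_radius_mm[i], spec.on_length_mm[i]
        a, wl = spec.on_sine_amplitude_mm[i], spec.on_sine_wavelength_mm[i]
        start = np.array([center[0] + side_sign * 13.0, center[1] - L / 2.0, z0])
        curve = sinusoid_centerline(start, np.array([0.0, 1.0, 0.0]),
                                    np.array([1.0, 0.0, 0.0]), L, a, wl)
        on_curves.append(curve)
        if r > 0:
            tube = make_tube_mask(curve, r, shape, tuple(sp))
            labels[tube & (labels == 0)] = lab

    # Meckel's caves: CSF blobs lateral-posterior, in free space
    for i, (side_sign, lab) in enumerate(((-1, 8), (1, 9))):
        r = spec.meckel_radius_mm[i]
        if r > 0:
            c = np.array([center[0] + side_sign * (spec.brain_semiaxes_mm[0] + r + 6.0),
                          center[1] - spec.brain_semiaxes_mm[1] * 0.6, center[2]])
            blob = _ellipsoid(shape, sp, c, (r, r, r))
            labels[blob & (labels == 0)] = lab

    # venous sinus: straight tube along the posterior midline shell
    if spec.sinus_radius_mm > 0:
        ztop = center[2] + spec.brain_semiaxes_mm[2] + spec.base_sas_thickness_mm / 2.0
        sinus_curve = np.stack([
            np.full(50, center[0]),
            np.linspace(center[1] - spec.brain_semiaxes_mm[1] * 0.9, center[1], 50),
            np.full(50, ztop),
        ], axis=1)
        tube = make_tube_mask(sinus_curve, spec.sinus_radius_mm, shape, tuple(sp))
        labels[tube & ~brain] = 10

    # intensity: CSF-like structures bright, tissue (brain + nerves) dark
    intensity = np.full(shape, spec.background, dtype=np.float64)
    intensity[np.isin(labels, (1, 6, 7))] = spec.tissue_low
    intensity[np.isin(labels, CSF_LIKE_LABELS)] = spec.csf_high
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=shape)

    # ROI masks emulate the manually drawn regional patches: compact and
    # interior, clear of sector seams, shell junctions and sheet rims where
    # medial widths are undefined
    dil = ndimage.generate_binary_structure(3, 3)
    roi_frontal = ndimage.binary_dilation(labels == 3, dil)
    roi_frontal &= np.broadcast_to(ygrid, shape) > center[1] + 0.5 * spec.brain_semiaxes_mm[1]
    xg = np.arange(shape[0])[:, None, None] * sp[0]
    zg = np.arange(shape[2])[None, None, :] * sp[2]
    q_brain = (
        ((np.broadcast_to(xg, shape) - center[0]) / spec.brain_semiaxes_mm[0]) ** 2
        + ((np.broadcast_to(ygrid, shape) - center[1]) / spec.brain_semiaxes_mm[1]) ** 2
        + ((np.broadcast_to(zg, shape) - center[2]) / spec.brain_semiaxes_mm[2]) ** 2
    )
    roi_ihf = ndimage.binary_dilation(labels == 4, dil)
    roi_ihf &= (q_brain <= 0.64) & (np.broadcast_to(zg, shape) >= center[2] + 4.0)
    roi_on = tuple(
        ndimage.binary_dilation(labels == lab, dil, iterations=3) for lab in (6, 7)
    )

    truth = PhantomTruth(
        fsas_mean_mm=spec.frontal_sas_thickness_mm,
        fsas_max_mm=spec.frontal_sas_thickness_mm,
        ihf_mean_mm=spec.ihf_width_mm,
        ihf_max_mm=spec.ihf_width_mm,
        on_arc_length_mm=tuple(
            sinusoid_arc_length(spec.on_length_mm[i], spec.on_sine_amplitude_mm[i],
                                spec.on_sine_wavelength_mm[i]) for i in (0, 1)
        ),
        on_chord_length_mm=tuple(float(L) for L in spec.on_length_mm),
        on_diameter_mm=tuple(2.0 * r for r in spec.on_radius_mm),
        on_arch_chord_ratio=tuple(
            sinusoid_arc_length(spec.on_length_mm[i], spec.on_sine_amplitude_mm[i],
                                spec.on_sine_wavelength_mm[i]) / spec.on_length_mm[i]
            if spec.on_length_mm[i] > 0 else 1.0
            for i in (0, 1)
        ),
        meckel_volume_mm3=tuple(4.0 / 3.0 * np.pi * r ** 3 for r in spec.meckel_radius_mm),
        roi_frontal=roi_frontal,
        roi_ihf=roi_ihf,
        roi_on=roi_on,
    )
    spacing = tuple(float(s) for s in sp)
    return (VoxelVolume(intensity, spacing), VoxelVolume(labels, spacing), truth)


def save_phantom(intensity: VoxelVolume, labels: VoxelVolume, truth: PhantomTruth,
                 out_dir: str | Path) -> dict:
    """Write intensity/labels as gzipped NIfTI-1 and truth as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensity": out / "intensity.nii.gz",
        "labels": out / "labels.nii.gz",
        "truth": out / "truth.json",
    }
    write_volume(intensity, paths["intensity"])
    write_volume(labels, paths["labels"])
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
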