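"""Voxelized volumes, DVH, and plan-quality indices.

Implements the slice-thickness voxelization study (how does the
reconstructed volume of a small sphere depend on CT slice thickness?)
and the standard stereotactic plan-quality metrics: cumulative DVH
and Dxx, Paddick conformity index, gradient index, the 12 Gy
efficiency index, and healthy-brain V12.

Volumes are voxel counts times voxel volume; isodose volumes use an
inclusive threshold (dose >= level).
"""

from __future__ import annotations

import numpy as np

from .plan_model import DoseGrid, StructureMask, ValidationError

__all__ = [
    "DVH",
    "voxelize_sphere",
    "structure_volume",
    "cumulative_dvh",
    "dose_at_volume",
    "isodose_volume",
    "paddick_ci",
    "gradient_index",
    "efficiency_index_12",
    "v12_healthy_brain",
]


class DVH:
    """Cumulative dose-volume histogram.

    ``volumes[i]`` is the structure volume (cm^3) receiving at least
    ``edges[i]`` Gy; ``volumes[0]`` equals the structure volume.
    """

    def __init__(self, edges: np.ndarray, volumes: np.ndarray):
        self.edges = np.asarray(edges, dtype=float)
        self.volumes = np.asarray(volumes, dtype=float)
        if self.edges.shape != self.volumes.shape:
            raise ValidationError("edges/volumes shape mismatch")
        if np.any(np.diff(self.volumes) > 1e-12):
            raise ValidationError("cumulative volume must be non-increasing")

    @property
    def structure_volume(self) -> float:
        return float(self.volumes[0]) if self.volumes.size else 0.0


def voxelize_sphere(
    diameter: float,
    in_plane_spacing: float,
    slice_thickness: float,
    center_offset=(0.0, 0.0, 0.0),
    padding_mm: float = 2.0,
) -> StructureMask:
    """Digitize a sphere on a grid with anisotropic z-spacing.

    A voxel belongs to the mask when its *center* lies inside the
    sphere (no partial-volume weighting) — the simplest reproducible
    surrogate for contouring a spherical target on CT slices of the
    given thickness.  ``center_offset`` shifts the sphere relative to
    the grid, exercising partial-volume variability.  A sphere smaller
    than the voxel may yield an empty mask.
    """
    if in_plane_spacing <= 0 or slice_thickness <= 0:
        raise ValidationError("spacings must be > 0")
    r = diameter / 2.0
    spacing = (in_plane_spacing, in_plane_spacing, slice_thickness)  # (x, y, z)
    half_extent = r + padding_mm
    ns = [int(np.ceil(2 * half_extent / s)) + 1 for s in spacing]
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * s - off
        for n, s, off in zip(ns, spacing, center_offset)
    ]
    zz, yy, xx = np.meshgrid(coords[2], coords[1], coords[0], indexing="ij")
    inside = xx**2 + yy**2 + zz**2 <= r**2
    origin = tuple(c[0] for c in coords)
    return StructureMask(inside, spacing, origin)


def structure_volume(mask: StructureMask) -> float:
    """Volume in cm^3: voxel count x voxel volume."""
    return float(mask.values.sum()) * mask.voxel_volume_cm3


def cumulative_dvh(dose: DoseGrid, mask: StructureMask, bin_width: float = 0.05) -> DVH:
    """Cumulative DVH of a structure on a matching dose grid."""
    if not mask.same_grid(dose):
        raise ValidationError("dose and mask grids do not match")
    vox = dose.values[mask.values]
    vol = mask.voxel_volume_cm3
    if vox.size == 0:
        edges = np.array([0.0])
        return DVH(edges, np.zeros(1))
    top = float(vox.max())
    n_bins = max(int(np.ceil(top / bin_width)) + 1, 2)
    edges = np.arange(n_bins + 1) * bin_width
    # volume receiving >= each edge
    counts = np.array([(vox >= e).sum() for e in edges], dtype=float)
    return DVH(edges, counts * vol)


def dose_at_volume(dvh: DVH, percent: float) -> float:
    """Dxx: the dose received by at least ``percent`` of the volume
    (percent a fraction in (0, 1]); linear interpolation between bins."""
    if not (0 < percent <= 1):
        raise ValidationError("percent must be in (0, 1]")
    total = dvh.structure_volume
    if total <= 0:
        raise ValidationError("empty DVH")
    target = percent * total
    vols = dvh.volumes
    edges = dvh.edges
    if target > vols[0]:
        return 0.0
    # volumes are non-increasing; find the last edge with volume >= target
    idx = np.where(vols >= target)[0]
    i = idx[-1]
    if i == len(vols) - 1 or vols[i] == target:
        return float(edges[i])
    v0, v1 = vols[i], vols[i + 1]
    e0, e1 = edges[i], edges[i + 1]
    if v0 == v1:
        return float(e0)
    frac = (v0 - target) / (v0 - v1)
    return float(e0 + frac * (e1 - e0))


def isodose_volume(dose: DoseGrid, level: float) -> float:
    """Volume (cm^3) receiving at least ``level`` Gy (inclusive)."""
    return float((dose.values >= level).sum()) * dose.voxel_volume_cm3


def _union_targets(target_masks) -> np.ndarray:
    masks = list(target_masks) if not isinstance(target_masks, StructureMask) else [target_masks]
    u = masks[0].values.copy()
    for m in masks[1:]:
        if not m.same_grid(masks[0]):
            raise ValidationError("target masks are on different grids")
        u |= m.values
    return u


def paddick_ci(dose: DoseGrid, target_masks, rx: float) -> float:
    """Paddick conformity index ``(TV n PIV)^2 / (TV * PIV)``.

    ``PIV`` is the prescription-isodose volume (dose >= rx); multiple
    targets are evaluated as their union.  Returns 0 when the PIV is
    empty.
    """
    if rx <= 0:
        raise ValidationError("rx must be > 0")
    tv = _union_targets(target_masks)
    piv = dose.values >= rx
    n_tv = tv.sum()
    n_piv = piv.sum()
    if n_piv == 0 or n_tv == 0:
        return 0.0
    n_int = (tv & piv).sum()
    return float(n_int) ** 2 / (float(n_tv) * float(n_piv))


def gradient_index(dose: DoseGrid, rx: float) -> float:
    """Gradient index ``V(rx/2) / V(rx)`` — dose fall-off steepness."""
    if rx <= 0:
        raise ValidationError("rx must be > 0")
    piv = isodose_volume(dose, rx)
    if piv == 0:
        raise ValidationError("prescription isodose volume is empty")
    return isodose_volume(dose, rx / 2.0) / piv


def efficiency_index_12(dose: DoseGrid, target_masks) -> float:
    """12 Gy efficiency index: ratio of the integral target dose to the
    integral dose of the volume receiving at least 12 Gy,
    ``sum_i(Dmean_TVi * TVi) / (Dmean_PIV12 * PIV12)``.
    """
    masks = [target_masks] if isinstance(target_masks, StructureMask) else list(target_masks)
    piv12 = dose.values >= 12.0
    if not piv12.any():
        raise ValidationError("no voxel receives 12 Gy")
    vol = dose.voxel_volume_cm3
    numer = 0.0
    for m in masks:
        if not m.same_grid(dose):
            raise ValidationError("target mask grid does not match dose grid")
        n = m.values.sum()
        if n == 0:
            continue
        numer += float(dose.values[m.values].mean()) * (n * vol)
    denom = float(dose.values[piv12].mean()) * (piv12.sum() * vol)
    return numer / denom


def v12_healthy_brain(
    dose: DoseGrid,
    brain: StructureMask,
    gtvs=(),
    brainstem: StructureMask | None = None,
    level: float = 12.0,
) -> float:
    """Healthy-brain V12 (cm^3): the healthy brain is the whole brain
    minus the GTVs and the brainstem; returns its volume receiving at
    least ``level`` Gy."""
    if not brain.same_grid(dose):
        raise ValidationError("brain mask grid does not match dose grid")
    healthy = brain.values.copy()
    for g in gtvs:
        if not g.same_grid(dose):
            raise ValidationError("GTV mask grid does not match dose grid")
        healthy &= ~g.values
    if brainstem is not None:
        if not brainstem.same_grid(dose):
            raise ValidationError("brainstem mask grid does not match dose grid")
        healthy &= ~brainstem.values
    hot = healthy & (dose.values >= level)
    return float(hot.sum()) * dose.voxel_volume_cm3
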