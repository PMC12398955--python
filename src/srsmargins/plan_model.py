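"""Domain types, unit conventions, file I/O and geometric utilities.

Units follow radiosurgery planning practice throughout the package:
distances and margins in millimetres, GTV equivalent diameter ("size")
in centimetres, volumes in cubic centimetres, dose in gray.  Patient
axes are x = left-right, y = anteroposterior, z = craniocaudal; 3-D
arrays are stored z-slowest (index order z, y, x), so the CT slice
thickness maps onto the leading array axis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LOBES",
    "Lesion",
    "Plan",
    "MarginVector",
    "DoseGrid",
    "StructureMask",
    "ValidationError",
    "equivalent_diameter",
    "sphere_volume",
    "expand_mask",
    "read_plan",
    "write_plan",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_grid",
    "write_grid",
]

#: Fixed brain-lobe vocabulary; anything else maps to "other".
LOBES = (
    "frontal",
    "parietal",
    "temporal",
    "occipital",
    "cerebellum",
    "brainstem",
    "other",
)

#: Tolerated relative disagreement between a stated volume and the
#: sphere volume implied by a stated equivalent diameter.
_SPHERE_CONSISTENCY_RTOL = 0.20


class ValidationError(ValueError):
    """A plan or lesion field violates its contract."""


def sphere_volume(diameter_cm: float) -> float:
    """Volume (cm^3) of a sphere of the given diameter (cm)."""
    return math.pi / 6.0 * diameter_cm**3


def equivalent_diameter(volume_cm3: float) -> float:
    """Sphere-equivalent diameter (cm) for a volume (cm^3).

    Inverse of :func:`sphere_volume`: ``d = (6 V / pi) ** (1/3)``.
    """
    if volume_cm3 <= 0:
        raise ValidationError(f"volume must be positive, got {volume_cm3}")
    return (6.0 * volume_cm3 / math.pi) ** (1.0 / 3.0)


@dataclass(frozen=True)
class Lesion:
    """One brain metastasis, located relative to the plan isocenter.

    Parameters
    ----------
    id : str
        Lesion identifier, unique within a plan.
    centroid : (3,) array-like, mm
        Centre of mass relative to the isocenter, (x, y, z) =
        (left-right, anteroposterior, craniocaudal).
    volume : float, cm^3
        GTV volume; must be positive.
    equiv_diameter : float or None, cm
        Sphere-equivalent GTV diameter.  Derived from ``volume`` when
        omitted; when both are given they must agree with the sphere
        relation within 20%.
    lobe : str
        Brain-lobe label from :data:`LOBES`; unknown labels map to
        ``"other"``.
    prescription : float, Gy
        Prescribed dose for this lesion.
    """

    id: str
    centroid: tuple[float, float, float]
    volume: float
    equiv_diameter: float | None = None
    lobe: str = "other"
    prescription: float = 21.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroid", tuple(float(c) for c in self.centroid))
        if len(self.centroid) != 3:
            raise ValidationError(f"lesion {self.id}: centroid must have 3 components")
        if not (self.volume > 0):
            raise ValidationError(f"lesion {self.id}: volume must be > 0, got {self.volume}")
        if self.equiv_diameter is None:
            object.__setattr__(self, "equiv_diameter", equivalent_diameter(self.volume))
        elif not (self.equiv_diameter > 0):
            raise ValidationError(
                f"lesion {self.id}: equiv_diameter must be > 0, got {self.equiv_diameter}"
            )
        else:
            implied = sphere_volume(self.equiv_diameter)
            if abs(implied - self.volume) > _SPHERE_CONSISTENCY_RTOL * self.volume:
                raise ValidationError(
                    f"lesion {self.id}: volume {self.volume} cm^3 and equiv_diameter "
                    f"{self.equiv_diameter} cm disagree with the sphere relation "
                    f"(implied volume {implied:.4g} cm^3) beyond 20%"
                )
        if self.lobe not in LOBES:
            object.__setattr__(self, "lobe", "other")
        if not (self.prescription > 0):
            raise ValidationError(
                f"lesion {self.id}: prescription must be > 0, got {self.prescription}"
            )

    @property
    def distance_to_isocenter(self) -> float:
        """Euclidean distance (mm) from the isocenter to the centroid."""
        return float(np.linalg.norm(self.centroid))

    @property
    def radius_mm(self) -> float:
        """Sphere-equivalent GTV radius in mm."""
        return self.equiv_diameter * 10.0 / 2.0


@dataclass(frozen=True)
class Plan:
    """A patient case: isocenter, lesions, CT and MLC geometry."""

    patient_id: str
    lesions: tuple[Lesion, ...]
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    slice_thickness: float = 1.0  # mm
    mlc_leaf_width: float = 2.5  # mm

    def __post_init__(self) -> None:
        object.__setattr__(self, "lesions", tuple(self.lesions))
        object.__setattr__(self, "isocenter", tuple(float(c) for c in self.isocenter))
        if len(self.lesions) < 1:
            raise ValidationError(f"plan {self.patient_id}: needs at least one lesion")
        if not (self.slice_thickness > 0):
            raise ValidationError(
                f"plan {self.patient_id}: slice_thickness must be > 0, got {self.slice_thickness}"
            )
        if not (self.mlc_leaf_width > 0):
            raise ValidationError(
                f"plan {self.patient_id}: mlc_leaf_width must be > 0, got {self.mlc_leaf_width}"
            )

    @property
    def n_metastases(self) -> int:
        return len(self.lesions)


@dataclass(frozen=True)
class MarginVector:
    """Anisotropic PTV margin (mm): anteroposterior, left-right, craniocaudal."""

    ap: float
    lr: float
    cc: float

    def __post_init__(self) -> None:
        for name, v in (("ap", self.ap), ("lr", self.lr), ("cc", self.cc)):
            if v < 0:
                raise ValidationError(f"margin component {name} must be >= 0, got {v}")

    @classmethod
    def isotropic(cls, value: float) -> "MarginVector":
        return cls(value, value, value)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.ap, self.lr, self.cc)


@dataclass
class DoseGrid:
    """Scalar dose field (Gy) on a regular grid; array stored (z, y, x)."""

    values: np.ndarray
    spacing: tuple[float, float, float]  # (x, y, z) mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.values.ndim != 3:
            raise ValidationError("dose values must be a 3-D array")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing components must be > 0, got {self.spacing}")
        if np.any(self.values < 0):
            raise ValidationError("dose values must be non-negative")

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class StructureMask:
    """Boolean structure field on the same grid convention as :class:`DoseGrid`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.values.ndim != 3:
            raise ValidationError("mask values must be a 3-D array")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def same_grid(self, other: "DoseGrid | StructureMask") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def expand_mask(mask: StructureMask, margin: MarginVector) -> StructureMask:
    """Dilate a mask with an ellipsoidal structuring element.

    The element's semi-axes are (lr, ap, cc) mm along (x, y, z),
    converted to voxels per axis; a voxel offset is inside the element
    when ``(dx/lr)^2 + (dy/ap)^2 + (dz/cc)^2 <= 1``.  A zero margin
    returns the mask unchanged.
    """
    semi_mm = np.array([margin.cc, margin.ap, margin.lr])  # (z, y, x) order
    if np.all(semi_mm == 0):
        return StructureMask(mask.values.copy(), mask.spacing, mask.origin)
    spacing_zyx = np.array(mask.spacing[::-1])
    extent_mm = np.array(mask.values.shape) * spacing_zyx
    if np.any(semi_mm > extent_mm):
        raise ValidationError("margin exceeds the grid extent")
    semi_vox = semi_mm / spacing_zyx
    half = np.ceil(semi_vox).astype(int)
    zz, yy, xx = np.mgrid[
        -half[0] : half[0] + 1, -half[1] : half[1] + 1, -half[2] : half[2] + 1
    ]
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = sum(
            np.where(s > 0, (c / np.maximum(s, 1e-300)) ** 2, np.where(c == 0, 0.0, np.inf))
            for c, s in zip((zz, yy, xx), semi_vox)
        )
    selem = r2 <= 1.0 + 1e-12
    out = ndimage.binary_dilation(mask.values, structure=selem)
    return StructureMask(out, mask.spacing, mask.origin)


# ---------------------------------------------------------------------------
# Plan file I/O (JSON) and cohort tables (CSV)
# ---------------------------------------------------------------------------

_LESION_KEYS = {"id", "centroid_mm", "volume_cm3", "equiv_diameter_cm", "lobe", "prescription_Gy"}


def _lesion_from_dict(d: dict, patient_id: str) -> Lesion:
    try:
        return Lesion(
            id=str(d["id"]),
            centroid=d["centroid_mm"],
            volume=float(d["volume_cm3"]),
            equiv_diameter=(
                float(d["equiv_diameter_cm"]) if d.get("equiv_diameter_cm") is not None else None
            ),
            lobe=str(d.get("lobe", "other")),
            prescription=float(d.get("prescription_Gy", 21.0)),
        )
    except KeyError as exc:
        raise ValidationError(f"plan {patient_id}: lesion missing field {exc}") from exc


def read_plan(path: str | Path) -> Plan:
    """Read and validate a plan JSON file.

    Schema: ``{patient_id, isocenter: [x,y,z], slice_thickness_mm,
    mlc_leaf_width_mm, lesions: [{id, centroid_mm, volume_cm3,
    equiv_diameter_cm, lobe, prescription_Gy}]}``.
    """
    with open(path) as fh:
        data = json.load(fh)
    for key in ("patient_id", "lesions"):
        if key not in data:
            raise ValidationError(f"plan file missing field '{key}'")
    return Plan(
        patient_id=str(data["patient_id"]),
        isocenter=tuple(data.get("isocenter", (0.0, 0.0, 0.0))),
        slice_thickness=float(data.get("slice_thickness_mm", 1.0)),
        mlc_leaf_width=float(data.get("mlc_leaf_width_mm", 2.5)),
        lesions=tuple(_lesion_from_dict(d, str(data["patient_id"])) for d in data["lesions"]),
    )


def write_plan(plan: Plan, path: str | Path) -> None:
    """Write a plan back to canonical JSON (sorted keys, 6-digit floats)."""
    data = {
        "patient_id": plan.patient_id,
        "isocenter": [round(c, 6) for c in plan.isocenter],
        "slice_thickness_mm": round(plan.slice_thickness, 6),
        "mlc_leaf_width_mm": round(plan.mlc_leaf_width, 6),
        "lesions": [
            {
                "id": les.id,
                "centroid_mm": [round(c, 6) for c in les.centroid],
                "volume_cm3": round(les.volume, 6),
                "equiv_diameter_cm": round(les.equiv_diameter, 6),
                "lobe": les.lobe,
                "prescription_Gy": round(les.prescription, 6),
            }
            for les in plan.lesions
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")


_COHORT_COLUMNS = [
    "patient_id",
    "id",
    "centroid_x_mm",
    "centroid_y_mm",
    "centroid_z_mm",
    "volume_cm3",
    "equiv_diameter_cm",
    "lobe",
    "prescription_Gy",
    "slice_thickness_mm",
    "mlc_leaf_width_mm",
]


def write_cohort_csv(plans: Sequence[Plan], path: str | Path) -> None:
    """One lesion per row; plan-level fields repeated on each row."""
    rows = []
    for plan in plans:
        for les in plan.lesions:
            rows.append(
                {
                    "patient_id": plan.patient_id,
                    "id": les.id,
                    "centroid_x_mm": les.centroid[0],
                    "centroid_y_mm": les.centroid[1],
                    "centroid_z_mm": les.centroid[2],
                    "volume_cm3": les.volume,
                    "equiv_diameter_cm": les.equiv_diameter,
                    "lobe": les.lobe,
                    "prescription_Gy": les.prescription,
                    "slice_thickness_mm": plan.slice_thickness,
                    "mlc_leaf_width_mm": plan.mlc_leaf_width,
                }
            )
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[Plan]:
    """Read a lesion-per-row cohort table back into plans."""
    df = pd.read_csv(path)
    plans: list[Plan] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        lesions = tuple(
            Lesion(
                id=str(r["id"]),
                centroid=(r["centroid_x_mm"], r["centroid_y_mm"], r["centroid_z_mm"]),
                volume=float(r["volume_cm3"]),
                equiv_diameter=float(r["equiv_diameter_cm"]),
                lobe=str(r["lobe"]),
                prescription=float(r["prescription_Gy"]),
            )
            for _, r in grp.iterrows()
        )
        plans.append(
            Plan(
                patient_id=str(pid),
                lesions=lesions,
                slice_thickness=float(grp["slice_thickness_mm"].iloc[0]),
                mlc_leaf_width=float(grp["mlc_leaf_width_mm"].iloc[0]),
            )
        )
    return plans


def write_grid(grid: DoseGrid | StructureMask, path: str | Path) -> None:
    """Write a grid to NRRD (or any format SimpleITK infers from the suffix)."""
    import SimpleITK as sitk

    arr = grid.values.astype(np.float32 if isinstance(grid, DoseGrid) else np.uint8)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(grid.spacing))
    img.SetOrigin(tuple(grid.origin))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_grid(path: str | Path, as_mask: bool = False) -> DoseGrid | StructureMask:
    """Read a NRRD/NIfTI grid; ``as_mask`` returns a boolean structure."""
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    spacing = tuple(img.GetSpacing())
    origin = tuple(img.GetOrigin())
    if as_mask:
        return StructureMask(arr > 0, spacing, origin)
    return DoseGrid(arr.astype(float), spacing, origin)
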