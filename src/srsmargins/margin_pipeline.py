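"""PTV margin assignment: geometric and optimized criteria.

Two criteria are implemented.  The geometric margin criterion (GMC)
is the conventional clinical rule: 0.5 mm isotropic for lesions
closer than 50 mm to the isocenter, 1.0 mm for distant (>= 50 mm) or
very small (< 0.1 cm^3) lesions.

The optimized margin criterion (OMC) runs a six-step pipeline per
lesion:

1. seed the margin with the maximum 6-DOF setup displacement of the
   lesion centroid (corner oracle, quantized to a 0.1 mm grid);
2. enlarge it until the sphere-equivalent PTV spans at least two MLC
   leaf widths;
3. enlarge it until the PTV reaches a minimum equivalent diameter
   (default 3 mm, so a 1 mm lesion receives a 1 mm margin);
4. (deployment) replace step 1 by a regression prediction clamped to
   the discrete [0.1, 1.0] mm range, then re-apply steps 2-3;
5. finalize anisotropically: anteroposterior/left-right take the
   predicted value, craniocaudal takes max(predicted, CT slice
   thickness);
6. attach the margins to the lesions (PTV construction is the mask
   layer's job).

Corrections 2-3 are safety rules and may exceed the 1.0 mm regressor
cap (a 2 mm lesion under a 2.5 mm leaf requires 1.5 mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .displacement import Tolerance6DOF, max_displacement_corners
from .plan_model import Lesion, MarginVector, Plan

__all__ = [
    "MarginPolicy",
    "quantize",
    "assign_gmc",
    "setup_margin",
    "mlc_correction",
    "min_volume_correction",
    "detect_clusters",
    "anisotropize",
    "expected_margin",
    "assign_omc",
]


@dataclass(frozen=True)
class MarginPolicy:
    """Tunable constants of the margin pipeline.

    quantum : margin grid step, mm.
    floor / cap : the discrete regressor output range, mm.
    min_ptv_diameter : smallest acceptable PTV equivalent diameter, mm.
    leaf_width : MLC leaf width, mm (PTV must span two leaves).
    cluster_buffer : added to the radius sum in the dose-cluster rule, mm.
    tol : 6-DOF setup tolerance for the displacement seed.
    """

    quantum: float = 0.1
    floor: float = 0.1
    cap: float = 1.0
    min_ptv_diameter: float = 3.0
    leaf_width: float = 2.5
    cluster_buffer: float = 6.0
    tol: Tolerance6DOF = field(default_factory=Tolerance6DOF)

    def __post_init__(self) -> None:
        if not (0 < self.floor <= self.cap):
            raise ValueError("need 0 < floor <= cap")
        if self.quantum <= 0:
            raise ValueError("quantum must be > 0")
        if self.min_ptv_diameter <= 0:
            raise ValueError("min_ptv_diameter must be > 0")


def quantize(value: float, quantum: float = 0.1) -> float:
    """Round half up onto the margin grid (0.44 -> 0.4, 0.45 -> 0.5).

    A tiny epsilon keeps binary-float representations of grid midpoints
    (0.35 stores as 0.34999...) on the intended side.
    """
    return round(math.floor(value / quantum + 0.5 + 1e-9) * quantum, 10)


def _clamp(value: float, lo: float, hi: float) -> float:
    return min(max(value, lo), hi)


def assign_gmc(plan: Plan) -> list[MarginVector]:
    """Isotropic margins by the geometric (distance/volume) criterion.

    0.5 mm when distance < 50 mm and volume >= 0.1 cm^3; 1.0 mm when
    distance >= 50 mm or volume < 0.1 cm^3 (boundaries on the
    conservative 1 mm side).
    """
    out = []
    for les in plan.lesions:
        if les.distance_to_isocenter < 50.0 and les.volume >= 0.1:
            out.append(MarginVector.isotropic(0.5))
        else:
            out.append(MarginVector.isotropic(1.0))
    return out


def setup_margin(lesion: Lesion, policy: MarginPolicy | None = None) -> float:
    """Step 1: quantized maximum setup displacement of the centroid (mm)."""
    policy = policy or MarginPolicy()
    disp = max_displacement_corners(lesion.centroid, policy.tol)
    return max(quantize(disp, policy.quantum), policy.floor)


def _grid_ceil(value: float, quantum: float) -> float:
    """Smallest grid multiple >= value."""
    return round(math.ceil(value / quantum - 1e-9) * quantum, 10)


def mlc_correction(margin: float, lesion: Lesion, leaf_width: float = 2.5, quantum: float = 0.1) -> float:
    """Step 2: grow the margin until the PTV spans two MLC leaves.

    The PTV equivalent diameter is ``10 * equiv_diameter + 2 * margin``
    (mm); the result is the smallest grid margin >= the input for
    which this reaches ``2 * leaf_width``.  May exceed the regressor
    cap — this is an absolute machine constraint.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    gtv_mm = lesion.equiv_diameter * 10.0
    needed = (2.0 * leaf_width - gtv_mm) / 2.0
    if needed <= margin:
        return margin
    return _grid_ceil(needed, quantum)


def min_volume_correction(
    margin: float, lesion: Lesion, min_ptv_diameter: float = 3.0, quantum: float = 0.1
) -> float:
    """Step 3: grow the margin until the PTV equivalent diameter reaches
    ``min_ptv_diameter`` (default 3 mm; a 1 mm lesion gets a 1 mm margin)."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    gtv_mm = lesion.equiv_diameter * 10.0
    needed = (min_ptv_diameter - gtv_mm) / 2.0
    if needed <= margin:
        return margin
    return _grid_ceil(needed, quantum)


def detect_clusters(plan: Plan, buffer: float = 6.0) -> tuple[list[bool], list[tuple[int, int]]]:
    """Dose-cluster detection: pair (i, j) clusters when the centroid
    distance is below the sphere-equivalent radius sum plus ``buffer``
    mm.  Returns per-lesion participation flags and the clustered pairs.
    """
    n = plan.n_metastases
    flags = [False] * n
    pairs: list[tuple[int, int]] = []
    cents = np.array([les.centroid for les in plan.lesions])
    radii = np.array([les.radius_mm for les in plan.lesions])
    for i in range(n):
        for j in range(i + 1, n):
            dist = float(np.linalg.norm(cents[i] - cents[j]))
            if dist < radii[i] + radii[j] + buffer:
                pairs.append((i, j))
                flags[i] = flags[j] = True
    return flags, pairs


def anisotropize(predicted: float, slice_thickness: float) -> MarginVector:
    """Step 5: ap/lr take the predicted margin, cc takes
    max(predicted, CT slice thickness)."""
    return MarginVector(ap=predicted, lr=predicted, cc=max(predicted, slice_thickness))


def expected_margin(lesion: Lesion, policy: MarginPolicy | None = None) -> float:
    """Training label: setup displacement passed through corrections 2-3,
    then clamped to the discrete regressor range [floor, cap]."""
    policy = policy or MarginPolicy()
    m = setup_margin(lesion, policy)
    m = mlc_correction(m, lesion, policy.leaf_width, policy.quantum)
    m = min_volume_correction(m, lesion, policy.min_ptv_diameter, policy.quantum)
    return _clamp(m, policy.floor, policy.cap)


def assign_omc(plan: Plan, model, policy: MarginPolicy | None = None) -> list[MarginVector]:
    """Optimized margin criterion: predict, clamp to the grid, re-apply
    the MLC and minimum-volume corrections, then finalize against the
    CT slice thickness.

    ``model`` is a fitted regressor exposing ``predict`` on the
    six-feature schema of :func:`srsmargins.regressors.build_features`.
    """
    from .regressors import build_features, features_to_matrix

    policy = policy or MarginPolicy()
    rows = build_features(plan, buffer=policy.cluster_buffer)
    preds = np.asarray(model.predict(features_to_matrix(rows)), dtype=float)
    out = []
    for les, raw in zip(plan.lesions, preds):
        pred = _clamp(quantize(float(raw), policy.quantum), policy.floor, policy.cap)
        m = mlc_correction(pred, les, policy.leaf_width, policy.quantum)
        m = min_volume_correction(m, les, policy.min_ptv_diameter, policy.quantum)
        out.append(anisotropize(m, plan.slice_thickness))
    return out
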