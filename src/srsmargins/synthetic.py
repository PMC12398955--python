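"""Synthetic cohorts and dose grids.

Generates patient plans whose lesion statistics emulate a published
multi-institutional SRS cohort: 2-40 metastases per patient (mean
about 6), right-skewed GTV volumes (mean 1.33 cm^3, sd 4.31, range
[0.01, 18.80]), and distances to the isocenter of 46 +/- 16 mm
(range [9, 101]).  Volumes are drawn from a truncated lognormal whose
location parameter is recalibrated so the *truncated* mean matches
the target (the upper truncation would otherwise bias the realized
mean low); distances from a truncated normal.

A per-lesion radial dose model stands in for a treatment planning
system: prescription dose inside the ellipsoidal PTV, falling
linearly at a fixed fraction of the prescription per millimetre
outside (default 16.6%/mm, the ideal fall-off from the prescription
isodose to half prescription), combined across lesions by voxelwise
maximum — which makes dose bridging between clustered lesions emerge
naturally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .margin_pipeline import MarginPolicy, expected_margin
from .plan_model import DoseGrid, Lesion, MarginVector, Plan, StructureMask

__all__ = [
    "CohortParams",
    "DoseModelParams",
    "generate_cohort",
    "generate_dose",
    "grid_geometry",
    "brain_mask",
    "lesion_masks",
    "ptv_masks",
    "make_training_set",
]

#: Default per-lesion brain-lobe sampling weights (uniform over the
#: common metastasis sites; the source cohort's lobe mix is unreported).
DEFAULT_LOBE_WEIGHTS = {
    "frontal": 1.0,
    "parietal": 1.0,
    "temporal": 1.0,
    "occipital": 1.0,
    "cerebellum": 1.0,
}

#: Brain modeled as an ellipsoid centred on the isocenter; semi-axes
#: (x=LR, y=AP, z=CC) in mm, sized to contain the distance range.
DEFAULT_BRAIN_SEMIAXES = (85.0, 110.0, 80.0)


@dataclass(frozen=True)
class CohortParams:
    """Sampling parameters for a synthetic cohort (units: mm, cm^3, Gy)."""

    n_patients: int = 50
    mets_mean: float = 6.0
    mets_sd: float = 6.0
    mets_range: tuple[int, int] = (2, 40)
    volume_mean: float = 1.33
    volume_sd: float = 4.31
    volume_range: tuple[float, float] = (0.01, 18.80)
    distance_mean: float = 46.0
    distance_sd: float = 16.0
    distance_range: tuple[float, float] = (9.0, 101.0)
    lobe_weights: dict = field(default_factory=lambda: dict(DEFAULT_LOBE_WEIGHTS))
    prescription: float = 21.0
    slice_thickness: float = 0.6
    mlc_leaf_width: float = 2.5
    brain_semiaxes: tuple[float, float, float] = DEFAULT_BRAIN_SEMIAXES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


@dataclass(frozen=True)
class DoseModelParams:
    """Radial dose fall-off model settings.

    falloff : dose loss per mm outside the PTV, as a fraction of the
        prescription (default 0.166 => half prescription ~3 mm out).
    spacing : isotropic dose-grid spacing, mm.
    """

    falloff: float = 0.166
    spacing: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.falloff <= 1):
            raise ValueError("falloff must be in (0, 1]")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")


def _lognormal_truncated_params(mean: float, sd: float, lo: float, hi: float):
    """Underlying (mu, sigma) whose [lo, hi]-truncated lognormal has the
    requested mean; sigma is moment-matched to the untruncated cv."""
    sigma = math.sqrt(math.log(1.0 + (sd / mean) ** 2))

    def trunc_mean(mu: float) -> float:
        a = (math.log(lo) - mu) / sigma
        b = (math.log(hi) - mu) / sigma
        mass = stats.norm.cdf(b) - stats.norm.cdf(a)
        # E[X; a < Z < b] for X = exp(mu + sigma Z)
        partial = math.exp(mu + sigma**2 / 2.0) * (
            stats.norm.cdf(b - sigma) - stats.norm.cdf(a - sigma)
        )
        return partial / mass

    mu0 = math.log(mean) - sigma**2 / 2.0
    mu = optimize.brentq(lambda m: trunc_mean(m) - mean, mu0 - 2.0, mu0 + 2.0)
    return mu, sigma


def _sample_truncated(rng, sampler, lo, hi, size, max_tries: int = 1000):
    """Rejection sampling into [lo, hi]."""
    out = np.empty(size)
    filled = 0
    for _ in range(max_tries):
        draw = sampler(rng, size - filled)
        keep = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
        if filled == size:
            return out
    raise RuntimeError("truncated sampling did not converge")


def generate_cohort(params: CohortParams | None = None) -> list[Plan]:
    """Sample a reproducible cohort of plans.

    Lesion centroids are placed at the sampled distance in a uniformly
    random direction, rejected when the GTV would leave the brain
    ellipsoid or overlap a previously placed GTV of the same plan.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(params.seed)
    v_mu, v_sigma = _lognormal_truncated_params(
        params.volume_mean, params.volume_sd, *params.volume_range
    )
    m_sigma = math.sqrt(math.log(1.0 + (params.mets_sd / params.mets_mean) ** 2))
    m_mu = math.log(params.mets_mean) - m_sigma**2 / 2.0
    lobes = list(params.lobe_weights)
    lobe_p = np.array(list(params.lobe_weights.values()), dtype=float)
    lobe_p = lobe_p / lobe_p.sum()
    semi = np.asarray(params.brain_semiaxes, dtype=float)

    plans: list[Plan] = []
    for ip in range(params.n_patients):
        n = int(
            _sample_truncated(
                rng,
                lambda r, k: np.round(r.lognormal(m_mu, m_sigma, size=k)),
                *params.mets_range,
                size=1,
            )[0]
        )
        volumes = _sample_truncated(
            rng, lambda r, k: r.lognormal(v_mu, v_sigma, size=k), *params.volume_range, size=n
        )
        distances = _sample_truncated(
            rng,
            lambda r, k: r.normal(params.distance_mean, params.distance_sd, size=k),
            *params.distance_range,
            size=n,
        )
        lesions: list[Lesion] = []
        placed: list[tuple[np.ndarray, float]] = []
        for j in range(n):
            radius = (6.0 * volumes[j] / math.pi) ** (1.0 / 3.0) * 10.0 / 2.0  # mm
            centroid = None
            for _ in range(2000):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cand = u * distances[j]
                inner = semi - radius
                if np.any(inner <= 0) or np.sum((cand / inner) ** 2) > 1.0:
                    continue
                if all(
                    np.linalg.norm(cand - c0) > radius + r0 for c0, r0 in placed
                ):
                    centroid = cand
                    break
            if centroid is None:
                raise RuntimeError(
                    f"could not place a non-overlapping GTV for patient {ip} "
                    f"(lesion {j}, distance {distances[j]:.1f} mm)"
                )
            placed.append((centroid, radius))
            lesions.append(
                Lesion(
                    id=f"L{j + 1}",
                    centroid=tuple(centroid),
                    volume=float(volumes[j]),
                    lobe=lobes[int(rng.choice(len(lobes), p=lobe_p))],
                    prescription=params.prescription,
                )
            )
        plans.append(
            Plan(
                patient_id=f"P{ip + 1:04d}",
                lesions=tuple(lesions),
                slice_thickness=params.slice_thickness,
                mlc_leaf_width=params.mlc_leaf_width,
            )
        )
    return plans


# ---------------------------------------------------------------------------
# Dose grids and structure masks on a per-plan grid
# ---------------------------------------------------------------------------


def grid_geometry(
    plan: Plan,
    margins: list[MarginVector],
    params: DoseModelParams,
    pad: float = 2.0,
):
    """Grid just covering every PTV plus the dose fall-off range.

    Returns (shape_zyx, spacing_xyz, origin_xyz); origin is the centre
    of voxel (0, 0, 0).
    """
    reach = 1.0 / params.falloff + pad
    half = np.zeros(3)
    for les, m in zip(plan.lesions, margins):
        ext = np.abs(les.centroid) + les.radius_mm + np.array(m.as_tuple())[[1, 0, 2]] + reach
        half = np.maximum(half, ext)  # (x, y, z)
    s = params.spacing
    ns = np.maximum(np.ceil(half / s).astype(int) * 2 + 1, 3)
    origin = -(ns - 1) / 2.0 * s  # (x, y, z)
    shape_zyx = tuple(int(v) for v in ns[::-1])
    return shape_zyx, (s, s, s), tuple(float(o) for o in origin)


def _axes(shape_zyx, spacing_xyz, origin_xyz):
    """Physical voxel-centre coordinates per axis, (z, y, x) order."""
    nz, ny, nx = shape_zyx
    sx, sy, sz = spacing_xyz
    ox, oy, oz = origin_xyz
    return (
        oz + np.arange(nz) * sz,
        oy + np.arange(ny) * sy,
        ox + np.arange(nx) * sx,
    )


def generate_dose(
    plan: Plan,
    margins: list[MarginVector],
    params: DoseModelParams | None = None,
    geometry=None,
) -> DoseGrid:
    """Synthetic plan dose: per lesion, prescription inside the
    ellipsoidal PTV and linear radial fall-off outside; voxelwise
    maximum across lesions.

    The distance outside an ellipsoid with semi-axes (a, b, c) is
    approximated by the radial gap ``||d|| (1 - 1/rho)`` with
    ``rho = sqrt((dx/a)^2 + (dy/b)^2 + (dz/c)^2)`` — exact for
    spheres and accurate for the near-spherical PTVs produced by
    sub-millimetre margins.
    """
    params = params or DoseModelParams()
    if len(margins) != plan.n_metastases:
        raise ValueError("one margin per lesion required")
    shape, spacing, origin = geometry or grid_geometry(plan, margins, params)
    z, y, x = _axes(shape, spacing, origin)
    dose = np.zeros(shape)
    reach = 1.0 / params.falloff
    for les, m in zip(plan.lesions, margins):
        r = les.radius_mm
        a, b, c = r + m.lr, r + m.ap, r + m.cc  # semi-axes along x, y, z
        cx, cy, cz = les.centroid
        lim = max(a, b, c) + reach + params.spacing
        iz = np.flatnonzero(np.abs(z - cz) <= lim)
        iy = np.flatnonzero(np.abs(y - cy) <= lim)
        ix = np.flatnonzero(np.abs(x - cx) <= lim)
        if not (len(iz) and len(iy) and len(ix)):
            raise ValueError("dose grid too small to contain the plan")
        dz = (z[iz] - cz)[:, None, None]
        dy = (y[iy] - cy)[None, :, None]
        dx = (x[ix] - cx)[None, None, :]
        rho = np.sqrt((dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2)
        rad = np.sqrt(dx**2 + dy**2 + dz**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            gap = np.where(rho > 1.0, rad * (1.0 - 1.0 / np.maximum(rho, 1e-12)), 0.0)
        local = les.prescription * np.clip(1.0 - params.falloff * gap, 0.0, 1.0)
        sub = dose[np.ix_(iz, iy, ix)]
        np.maximum(sub, local, out=sub)
        dose[np.ix_(iz, iy, ix)] = sub
    return DoseGrid(dose, spacing, origin)


def _ellipsoid_mask(shape, spacing, origin, center, semiaxes) -> np.ndarray:
    z, y, x = _axes(shape, spacing, origin)
    cx, cy, cz = center
    a, b, c = semiaxes  # along x, y, z
    dz = ((z - cz) / c)[:, None, None]
    dy = ((y - cy) / b)[None, :, None]
    dx = ((x - cx) / a)[None, None, :]
    return dx**2 + dy**2 + dz**2 <= 1.0


def brain_mask(shape, spacing, origin, semiaxes=DEFAULT_BRAIN_SEMIAXES) -> StructureMask:
    """Ellipsoidal whole-brain mask centred on the isocenter."""
    return StructureMask(
        _ellipsoid_mask(shape, spacing, origin, (0.0, 0.0, 0.0), semiaxes), spacing, origin
    )


def lesion_masks(plan: Plan, shape, spacing, origin) -> list[StructureMask]:
    """Sphere-equivalent GTV masks on the plan grid."""
    return [
        StructureMask(
            _ellipsoid_mask(
                shape, spacing, origin, les.centroid, (les.radius_mm,) * 3
            ),
            spacing,
            origin,
        )
        for les in plan.lesions
    ]


def ptv_masks(plan: Plan, margins: list[MarginVector], shape, spacing, origin) -> list[StructureMask]:
    """Ellipsoidal PTV masks (GTV radius plus the anisotropic margin)."""
    return [
        StructureMask(
            _ellipsoid_mask(
                shape,
                spacing,
                origin,
                les.centroid,
                (les.radius_mm + m.lr, les.radius_mm + m.ap, les.radius_mm + m.cc),
            ),
            spacing,
            origin,
        )
        for les, m in zip(plan.lesions, margins)
    ]


def make_training_set(cohort: list[Plan], policy: MarginPolicy | None = None):
    """Feature rows plus expected-margin labels for a whole cohort."""
    import warnings

    from .regressors import RegressionDataset, build_features

    policy = policy or MarginPolicy()
    rows = []
    labels = []
    for plan in cohort:
        rows.extend(build_features(plan, buffer=policy.cluster_buffer))
        labels.extend(expected_margin(les, policy) for les in plan.lesions)
    if len(set(np.round(np.asarray(labels) * 10).astype(int))) < 2:
        warnings.warn("degenerate training set: a single label value", stacklevel=2)
    return RegressionDataset(rows=rows, labels=np.asarray(labels))
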