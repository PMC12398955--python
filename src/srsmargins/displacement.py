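"""Maximum target displacement under 6-DOF setup tolerances.

In single-isocenter multiple-metastases radiosurgery every lesion
shares one rotation centre, so a small rotational setup error
displaces off-axis targets by roughly ``distance x angle``.  The
margin seed for each lesion is the largest displacement its centroid
can undergo under symmetric per-axis rotation/translation tolerances
(default 0.2 degrees / 0.2 mm).

Two maximizers are provided: an exhaustive corner enumeration (the
deterministic oracle — for box-bounded rigid motions the maximum of
the displacement norm is attained at a sign corner) and a genetic
algorithm searching the continuous 6-D tolerance box.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Tolerance6DOF",
    "GAParams",
    "ROTATION_ORDERS",
    "rigid_displacement",
    "max_displacement_corners",
    "max_displacement_grid",
    "max_displacement_ga",
]

#: The six intrinsic rotation-axis orderings.
ROTATION_ORDERS = ("XYZ", "XZY", "YXZ", "YZX", "ZXY", "ZYX")


@dataclass(frozen=True)
class Tolerance6DOF:
    """Symmetric per-axis setup tolerance: rotation (deg) and translation (mm)."""

    rot: float = 0.2
    trans: float = 0.2

    def __post_init__(self) -> None:
        if self.rot < 0 or self.trans < 0:
            raise ValueError("tolerances must be non-negative")


@dataclass(frozen=True)
class GAParams:
    """Genetic-algorithm settings for the continuous 6-D box search."""

    population_size: int = 50
    generations: int = 100
    mutation_rate: float = 0.1
    crossover_rate: float = 0.9
    tournament_size: int = 3
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("mutation_rate", "crossover_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


def rigid_displacement(
    point,
    angles,
    translation,
    order: str = "XYZ",
) -> float:
    """Displacement ``||R(angles) p + t - p||`` of a point under a rigid motion.

    Rotations are intrinsic, about the patient axes in the given order,
    centred at the isocenter (the origin of the centroid frame); angles
    in degrees, translations in mm.
    """
    p = np.asarray(point, dtype=float)
    r = Rotation.from_euler(order, np.asarray(angles, dtype=float), degrees=True)
    moved = r.apply(p) + np.asarray(translation, dtype=float)
    return float(np.linalg.norm(moved - p))


def _displacements_batch(p: np.ndarray, angles: np.ndarray, trans: np.ndarray, order: str):
    """Vectorized ``||R p + t - p||`` for stacked (n, 3) angles/translations."""
    r = Rotation.from_euler(order, angles, degrees=True)
    moved = r.apply(np.broadcast_to(p, angles.shape).copy()) + trans
    return np.linalg.norm(moved - p, axis=1)


def _orders(order: str | None) -> tuple[str, ...]:
    if order is None:
        return ROTATION_ORDERS
    if order not in ROTATION_ORDERS:
        raise ValueError(f"unknown rotation order {order!r}")
    return (order,)


def max_displacement_corners(
    point,
    tol: Tolerance6DOF,
    order: str | None = None,
) -> float:
    """Maximum displacement over the tolerance box by corner enumeration.

    Evaluates the 2^3 rotation-sign corners x 2^3 translation-sign
    corners, maximized over all six rotation-axis orderings (or one
    fixed ordering if given).  Deterministic; serves as the oracle for
    the genetic search.
    """
    p = np.asarray(point, dtype=float)
    signs = np.array(list(itertools.product((-1.0, 1.0), repeat=3)))
    angles = signs * tol.rot  # (8, 3)
    trans = signs * tol.trans  # (8, 3)
    ang_all = np.repeat(angles, 8, axis=0)
    trn_all = np.tile(trans, (8, 1))
    best = 0.0
    for ordr in _orders(order):
        best = max(best, float(_displacements_batch(p, ang_all, trn_all, ordr).max()))
    return best


def max_displacement_grid(
    point,
    tol: Tolerance6DOF,
    n_per_axis: int = 21,
    order: str | None = None,
) -> float:
    """Dense-grid reference: ``n_per_axis`` points per rotation axis.

    For each candidate rotation the translation is chosen in closed
    form: ``t_i = trans * sign(d_i)`` with ``d = R p - p`` maximizes
    ``||d + t||`` over the translation box.
    """
    p = np.asarray(point, dtype=float)
    axis = np.linspace(-tol.rot, tol.rot, n_per_axis)
    grid = np.array(list(itertools.product(axis, repeat=3)))
    best = 0.0
    for ordr in _orders(order):
        r = Rotation.from_euler(ordr, grid, degrees=True)
        d = r.apply(np.broadcast_to(p, grid.shape).copy()) - p
        t = tol.trans * np.sign(d)
        t[np.abs(d) < 1e-300] = tol.trans  # any sign is optimal at a zero component
        best = max(best, float(np.linalg.norm(d + t, axis=1).max()))
    return best


def max_displacement_ga(
    point,
    tol: Tolerance6DOF,
    params: GAParams | None = None,
    order: str | None = None,
) -> float:
    """Genetic-algorithm maximization over the continuous 6-D tolerance box.

    Genome = (3 angles, 3 translations); tournament selection, uniform
    crossover, per-gene Gaussian mutation clipped to the box (clipping
    lets genes settle on the box faces, where the optimum lies), and
    elitism.  Fitness uses the same objective definition as the corner
    oracle (max over rotation orderings unless one is fixed).
    Reproducible for a given seed.
    """
    params = params or GAParams()
    p = np.asarray(point, dtype=float)
    rng = np.random.default_rng(params.seed)
    lo = np.array([-tol.rot] * 3 + [-tol.trans] * 3)
    hi = -lo
    span = hi - lo
    orders = _orders(order)

    def fitness(pop: np.ndarray) -> np.ndarray:
        ang, trn = pop[:, :3], pop[:, 3:]
        vals = np.zeros(len(pop))
        for ordr in orders:
            np.maximum(vals, _displacements_batch(p, ang, trn, ordr), out=vals)
        return vals

    n = params.population_size
    pop = rng.uniform(lo, hi, size=(n, 6))
    fit = fitness(pop)
    for _ in range(params.generations):
        # tournament selection of parents
        idx = rng.integers(0, n, size=(n, params.tournament_size))
        winners = idx[np.arange(n), np.argmax(fit[idx], axis=1)]
        parents = pop[winners]
        # uniform crossover between consecutive parent pairs
        children = parents.copy()
        do_cx = rng.random(n // 2) < params.crossover_rate
        swap = rng.random((n // 2, 6)) < 0.5
        a, b = children[0::2], children[1::2]
        mask = swap & do_cx[:, None]
        a[mask], b[mask] = b[mask], a[mask]
        # Gaussian mutation, clipped to the box; a fraction of mutations
        # snap the gene to a box face, where the optimum lies
        mut = rng.random(children.shape) < params.mutation_rate
        children = children + mut * rng.normal(0.0, 0.1, children.shape) * span
        snap = rng.random(children.shape) < params.mutation_rate * 0.5
        faces = np.where(rng.random(children.shape) < 0.5, lo, hi)
        children = np.where(snap, faces, children)
        # sign-flip mutation: jump between symmetric corners (the box
        # landscape is multi-modal in the sign pattern)
        flip_child = rng.random(n) < 0.1
        flip_gene = rng.random(children.shape) < 0.5
        children = np.where(flip_child[:, None] & flip_gene, -children, children)
        children = np.clip(children, lo, hi)
        child_fit = fitness(children)
        # elitism: carry the current best through unchanged
        if params.elitism > 0:
            elite = np.argsort(fit)[-params.elitism :]
            worst = np.argsort(child_fit)[: params.elitism]
            children[worst] = pop[elite]
            child_fit[worst] = fit[elite]
        pop, fit = children, child_fit
    return float(fit.max())


def translation_only_displacement(tol: Tolerance6DOF) -> float:
    """Closed form for the rotation-free case: ``sqrt(3) * trans``."""
    return math.sqrt(3.0) * tol.trans
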