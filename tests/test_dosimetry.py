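import math

import numpy as np
import pytest

from srsmargins.dosimetry import (
    DVH,
    cumulative_dvh,
    dose_at_volume,
    efficiency_index_12,
    gradient_index,
    paddick_ci,
    structure_volume,
    v12_healthy_brain,
    voxelize_sphere,
)
from srsmargins.plan_model import DoseGrid, StructureMask, ValidationError


def _uniform_grid(shape=(10, 10, 10), spacing=1.0, value=0.0):
    return DoseGrid(np.full(shape, value), (spacing, spacing, spacing))


def _mask_like(dose, region):
    vals = np.zeros(dose.values.shape, dtype=bool)
    vals[region] = True
    return StructureMask(vals, dose.spacing, dose.origin)


class TestVoxelization:
    def test_fine_grid_matches_analytic_volume(self):
        mask = voxelize_sphere(10.0, 0.5, 0.5)
        analytic = 4 / 3 * math.pi * 5**3 / 1000.0
        assert structure_volume(mask) == pytest.approx(analytic, rel=0.02)

    def test_thick_slices_worse_than_thin_for_small_spheres(self):
        rng = np.random.default_rng(0)
        analytic = 4 / 3 * math.pi * 3**3 / 1000.0  # 6 mm sphere
        errors = {}
        for thickness in (0.6, 2.0):
            errs = []
            for _ in range(20):
                off = rng.uniform(-1, 1, 3) * (0.5, 0.5, thickness / 2)
                vol = structure_volume(voxelize_sphere(6.0, 0.5, thickness, off))
                errs.append(abs(vol - analytic))
            errors[thickness] = np.mean(errs)
        assert errors[2.0] > errors[0.6]

    def test_relative_error_shrinks_with_diameter(self):
        rng = np.random.default_rng(1)
        rel = []
        for d in (6.0, 15.0):
            analytic = math.pi / 6 * d**3 / 1000.0
            errs = [
                abs(
                    structure_volume(
                        voxelize_sphere(d, 1.0, 1.0, rng.uniform(-0.5, 0.5, 3))
                    )
                    - analytic
                )
                / analytic
                for _ in range(10)
            ]
            rel.append(np.mean(errs))
        assert rel[1] < rel[0]

    def test_sub_voxel_sphere_may_be_empty(self):
        mask = voxelize_sphere(0.4, 1.0, 2.0, (0.3, 0.3, 0.7))
        assert structure_volume(mask) == 0.0


class TestDVH:
    def test_uniform_dose_step_function(self):
        dose = _uniform_grid(value=21.0)
        mask = _mask_like(dose, (slice(2, 5), slice(2, 5), slice(2, 5)))
        dvh = cumulative_dvh(dose, mask)
        vol = 27 / 1000.0
        assert dvh.structure_volume == pytest.approx(vol)
        assert dose_at_volume(dvh, 0.99) == pytest.approx(21.0, abs=0.06)

    def test_half_and_half(self):
        dose = _uniform_grid()
        dose.values[:5] = 10.0
        dose.values[5:] = 20.0
        mask = _mask_like(dose, (slice(None), slice(None), slice(None)))
        dvh = cumulative_dvh(dose, mask)
        # V(15 Gy) = half the volume
        i = np.searchsorted(dvh.edges, 15.0)
        assert dvh.volumes[i] == pytest.approx(0.5 * dvh.structure_volume)

    def test_empty_mask_all_zero(self):
        dose = _uniform_grid(value=5.0)
        mask = _mask_like(dose, (slice(0, 0), slice(0, 0), slice(0, 0)))
        dvh = cumulative_dvh(dose, mask)
        assert dvh.structure_volume == 0.0
        with pytest.raises(ValidationError):
            dose_at_volume(dvh, 0.99)

    def test_grid_mismatch_rejected(self):
        dose = _uniform_grid()
        mask = StructureMask(np.ones((5, 5, 5), dtype=bool), (1, 1, 1))
        with pytest.raises(ValidationError):
            cumulative_dvh(dose, mask)

    def test_linear_ramp_d99(self):
        # dose rises linearly 0 -> 20 Gy along z across the mask
        n = 200
        vals = np.tile(np.linspace(0, 20, n)[:, None, None], (1, 4, 4))
        dose = DoseGrid(vals, (1, 1, 1))
        mask = _mask_like(dose, (slice(None), slice(None), slice(None)))
        dvh = cumulative_dvh(dose, mask, bin_width=0.01)
        assert dose_at_volume(dvh, 0.99) == pytest.approx(0.2, abs=0.06)
        assert dose_at_volume(dvh, 0.99) <= dose_at_volume(dvh, 0.50)


class TestPaddick:
    def test_perfect_conformity(self):
        dose = _uniform_grid()
        region = (slice(2, 6), slice(2, 6), slice(2, 6))
        dose.values[region] = 21.0
        mask = _mask_like(dose, region)
        assert paddick_ci(dose, mask, 21.0) == pytest.approx(1.0)

    def test_double_piv_halves_index(self):
        dose = _uniform_grid()
        dose.values[2:4] = 21.0  # PIV: 2 slabs
        mask = _mask_like(dose, (slice(2, 3), slice(None), slice(None)))  # TV: 1 slab
        assert paddick_ci(dose, mask, 21.0) == pytest.approx(0.5)

    def test_disjoint_dose_and_target(self):
        dose = _uniform_grid()
        dose.values[0:2] = 21.0
        mask = _mask_like(dose, (slice(8, 10), slice(None), slice(None)))
        assert paddick_ci(dose, mask, 21.0) == 0.0

    def test_no_piv_returns_zero(self):
        dose = _uniform_grid(value=1.0)
        mask = _mask_like(dose, (slice(2, 4), slice(None), slice(None)))
        assert paddick_ci(dose, mask, 21.0) == 0.0


class TestGradientIndex:
    def test_uniform_prescription_gi_is_one(self):
        dose = _uniform_grid()
        dose.values[3:6] = 21.0
        assert gradient_index(dose, 21.0) == pytest.approx(1.0)

    def test_radial_falloff_sphere(self):
        # 21 Gy inside R = 10 mm, falling 16.6% of rx per mm outside:
        # half dose at R + 3.01 mm -> GI ~ (13/10)^3
        n = 81
        c = (np.arange(n) - n // 2) * 0.5
        zz, yy, xx = np.meshgrid(c, c, c, indexing="ij")
        r = np.sqrt(xx**2 + yy**2 + zz**2)
        vals = 21.0 * np.clip(1.0 - 0.166 * np.clip(r - 10.0, 0, None), 0, 1)
        dose = DoseGrid(vals, (0.5, 0.5, 0.5))
        assert gradient_index(dose, 21.0) == pytest.approx(2.197, rel=0.02)

    def test_gi_at_least_one(self):
        dose = _uniform_grid()
        dose.values[4:6] = 25.0
        dose.values[2:4] = 12.0
        assert gradient_index(dose, 21.0) >= 1.0

    def test_empty_piv_rejected(self):
        with pytest.raises(ValidationError):
            gradient_index(_uniform_grid(value=1.0), 21.0)


class TestEfficiencyIndex:
    def test_dose_only_on_target(self):
        dose = _uniform_grid()
        region = (slice(2, 6), slice(2, 6), slice(2, 6))
        dose.values[region] = 21.0
        mask = _mask_like(dose, region)
        assert efficiency_index_12(dose, mask) == pytest.approx(1.0)

    def test_two_targets_double_piv(self):
        dose = _uniform_grid()
        dose.values[0:4] = 20.0  # PIV12 = 4 slabs at equal dose
        t1 = _mask_like(dose, (slice(0, 1), slice(None), slice(None)))
        t2 = _mask_like(dose, (slice(1, 2), slice(None), slice(None)))
        assert efficiency_index_12(dose, [t1, t2]) == pytest.approx(0.5)

    def test_bounded_by_one_when_targets_covered(self):
        dose = _uniform_grid()
        dose.values[2:8] = 18.0
        mask = _mask_like(dose, (slice(3, 5), slice(2, 5), slice(2, 5)))
        ei = efficiency_index_12(dose, mask)
        assert 0 < ei <= 1.0

    def test_no_12gy_volume_rejected(self):
        dose = _uniform_grid(value=5.0)
        mask = _mask_like(dose, (slice(2, 4), slice(None), slice(None)))
        with pytest.raises(ValidationError):
            efficiency_index_12(dose, mask)


class TestV12:
    def test_set_arithmetic(self):
        # 12 Gy over 2 cm^3 of brain, 0.5 cm^3 of it inside a GTV
        dose = _uniform_grid(shape=(20, 20, 20))
        dose.values[0:5] = 12.0  # 2 cm^3 hot
        brain = _mask_like(dose, (slice(None), slice(None), slice(None)))
        gtv = _mask_like(dose, (slice(0, 5), slice(0, 10), slice(0, 10)))  # 0.5 cm^3, all hot
        v12 = v12_healthy_brain(dose, brain, gtvs=[gtv])
        assert v12 == pytest.approx(2.0 - 0.5)

    def test_cold_plan_gives_zero(self):
        dose = _uniform_grid(value=5.0)
        brain = _mask_like(dose, (slice(None), slice(None), slice(None)))
        assert v12_healthy_brain(dose, brain) == 0.0

    def test_gtv_covering_dose_gives_zero(self):
        dose = _uniform_grid()
        dose.values[2:4] = 15.0
        brain = _mask_like(dose, (slice(None), slice(None), slice(None)))
        gtv = _mask_like(dose, (slice(2, 4), slice(None), slice(None)))
        assert v12_healthy_brain(dose, brain, gtvs=[gtv]) == 0.0

    def test_monotone_in_dose_scaling(self):
        dose = _uniform_grid()
        dose.values[:] = np.linspace(0, 14, 10)[:, None, None]
        brain = _mask_like(dose, (slice(None), slice(None), slice(None)))
        v1 = v12_healthy_brain(dose, brain)
        scaled = DoseGrid(dose.values * 1.5, dose.spacing, dose.origin)
        assert v12_healthy_brain(scaled, brain) >= v1

    def test_brainstem_excluded(self):
        dose = _uniform_grid()
        dose.values[2:4] = 15.0
        brain = _mask_like(dose, (slice(None), slice(None), slice(None)))
        stem = _mask_like(dose, (slice(2, 3), slice(None), slice(None)))
        with_stem = v12_healthy_brain(dose, brain, brainstem=stem)
        without = v12_healthy_brain(dose, brain)
        assert with_stem == pytest.approx(without - 0.1)
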