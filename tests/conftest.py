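import math

import numpy as np
import pytest

from srsmargins.plan_model import Lesion, Plan


def sphere_lesion(lesion_id, centroid, diameter_cm, **kw):
    """Lesion with volume derived from a sphere of the given diameter."""
    return Lesion(
        id=lesion_id,
        centroid=centroid,
        volume=math.pi / 6.0 * diameter_cm**3,
        **kw,
    )


@pytest.fixture
def single_lesion_plan():
    return Plan("p1", (sphere_lesion("L1", (30.0, 0.0, 0.0), 1.0),), slice_thickness=1.0)


@pytest.fixture
def two_lesion_plan():
    # r = 5 mm each, centres 15 mm apart -> clustered (15 < 5+5+6)
    return Plan(
        "p2",
        (
            sphere_lesion("L1", (20.0, 0.0, 0.0), 1.0),
            sphere_lesion("L2", (35.0, 0.0, 0.0), 1.0),
        ),
    )


@pytest.fixture(scope="session")
def small_cohort():
    from srsmargins.synthetic import CohortParams, generate_cohort

    return generate_cohort(CohortParams(n_patients=40, seed=123))


@pytest.fixture(scope="session")
def random_points():
    rng = np.random.default_rng(42)
    pts = rng.normal(size=(200, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= (rng.uniform(0, 1, 200) ** (1 / 3) * 100)[:, None]
    return pts
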