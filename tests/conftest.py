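import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from scovmap.io_grid import SubjectCohort, VolumeGrid
from scovmap.synthetic import (
    CohortSpec,
    NetworkNodeSpec,
    ScoreModel,
    default_grid,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def unit_grid():
    """8x8x8 grid with identity affine (1 mm voxels at integer mm)."""
    return VolumeGrid(dims=(8, 8, 8), affine=np.eye(4))


@pytest.fixture
def mm4_grid():
    """Small 4 mm isotropic grid with a centered world origin."""
    return default_grid(dims=(20, 20, 20), voxel_mm=4.0)


def make_cohort(grid, gm, groups, **columns):
    """Cohort from raw arrays, with ids generated per group."""
    counters = {}
    ids = []
    for g in groups:
        counters[g] = counters.get(g, 0) + 1
        ids.append(f"{g}{counters[g]:02d}")
    table = pd.DataFrame({"id": ids, "group": list(groups), **columns})
    return SubjectCohort(grid=grid, gm=np.asarray(gm, dtype=float), table=table)


def compact_spec(**overrides):
    """Small two-node cohort spec for fast unit tests.

    Grid 20^3 at 4 mm (world +-38 mm), spherical support of radius 30 mm,
    a 6 mm seed node shared by both groups and one extra node in group A.
    """
    grid = default_grid(dims=(20, 20, 20), voxel_mm=4.0)
    seed = NetworkNodeSpec("seed", (10.0, 8.0, -4.0), 6.0, 0.15)
    node2 = NetworkNodeSpec("node2", (-12.0, -8.0, 8.0), 6.0, 0.15)
    base = dict(
        grid=grid,
        n_per_group=8,
        networks={"A": (seed, node2), "B": (seed,)},
        support_semiaxes_mm=(30.0, 30.0, 30.0),
        noise_sd=0.08,
        noise_fwhm_mm=8.0,
        score=ScoreModel(intercept={"A": 0.7, "B": 9.5}, slope=2.0, noise_sd=1.0),
        rng_seed=0,
    )
    base.update(overrides)
    return CohortSpec(**base)
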