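import numpy as np
import pytest

from radpheno import CohortSpec, RunConfig, VolumeWithMask, generate_cohort
from radpheno.pipeline import run_pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    """A 16^3 random-intensity volume with a blobby central mask."""
    shape = (16, 16, 16)
    x, y, z = np.mgrid[0:16, 0:16, 0:16]
    mask = (x - 8) ** 2 + (y - 8) ** 2 + (z - 8) ** 2 <= 36
    return VolumeWithMask(rng.normal(100, 10, shape), (1.0, 1.0, 1.0), mask)


def sphere_volume(radius_mm, spacing, pad_mm=3.0, value=1.0):
    """A constant-intensity sphere phantom (mask = sphere) for analytic tests."""
    spacing = np.asarray(spacing, dtype=float)
    half = radius_mm + pad_mm
    # odd voxel counts so a voxel center sits exactly at the sphere center
    shape = (2 * np.ceil(half / spacing) + 1).astype(int)
    grids = np.meshgrid(
        *[(np.arange(n) - (n - 1) / 2) * s for n, s in zip(shape, spacing)],
        indexing="ij",
    )
    r2 = sum(g**2 for g in grids)
    mask = r2 <= radius_mm**2
    return VolumeWithMask(np.full(tuple(shape), value), tuple(spacing), mask)


# A compact cohort spec for pipeline-level tests: a flatter class balance
# so every endpoint has enough training patients, and tumors large enough
# (5.5-8 mm radius) for the rim/core texture cues to be well expressed.
SMALL_COHORT = dict(
    n_patients=48,
    prevalence=(0.35, 0.30, 0.35),
    shape=(32, 32, 32),
    radius_range_mm=(5.5, 8.0),
    n_resegmented=8,
    seed=424242,
)


@pytest.fixture(scope="session")
def small_report():
    """One full pipeline run on a compact synthetic cohort, shared by tests."""
    config = RunConfig(cohort=CohortSpec(**SMALL_COHORT), seed=3)
    return run_pipeline(config)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortSpec(**SMALL_COHORT))
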