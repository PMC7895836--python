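import numpy as np
import pytest

from ectfield import Grid, SubjectFieldStack, SyntheticSpec, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_grid():
    affine = np.diag([4.0, 4.0, 4.0, 1.0])
    affine[:3, 3] = [-10.0, -10.0, -10.0]
    return Grid(shape=(6, 6, 6), affine=affine)


@pytest.fixture
def small_stack(small_grid, rng):
    """10 subjects on a 6x6x6 grid, full mask, random positive fields."""
    mask = np.ones(small_grid.shape, dtype=bool)
    data = rng.lognormal(mean=4.0, sigma=0.3, size=(10, mask.sum()))
    ids = [f"s{i:02d}" for i in range(10)]
    return SubjectFieldStack(grid=small_grid, subject_ids=ids, data=data, mask=mask)


@pytest.fixture(scope="session")
def tiny_spec():
    """Desk-scale synthetic settings shared by integration tests."""
    return SyntheticSpec(
        shape=(12, 14, 12),
        n_rul_only=8,
        n_bl_only=8,
        n_switchers=8,
        effect_center=(3, 8, 5),
        effect_radius_vox=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_spec):
    return generate_study(tiny_spec)
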