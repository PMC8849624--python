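import numpy as np
import pytest

from astrodensity.morphology import (MorphologyParams, cube_cover,
                                     generate_astrocyte, morphometrics)

ENSEMBLE_SEEDS = tuple(range(10))


@pytest.fixture(scope="session")
def ensemble():
    """Ten model astrocytes with default parameters (fixed seed list)."""
    return [generate_astrocyte(MorphologyParams(), seed=s) for s in ENSEMBLE_SEEDS]


@pytest.fixture(scope="session")
def ensemble_stats(ensemble):
    """Morphometrics and cube-cover statistics for the shared ensemble."""
    rows = []
    for model in ensemble:
        m = morphometrics(model)
        cc = cube_cover(model)
        rows.append((m, cc))
    return rows


@pytest.fixture(scope="session")
def small_cell():
    """One compact cell for packing/classification tests."""
    params = MorphologyParams(n_primary_range=(3, 3), max_primary_branchpoints=5,
                              max_levels=5, segment_baseline_max=8.0)
    return generate_astrocyte(params, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
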