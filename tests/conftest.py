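import numpy as np
import pytest

import legnet


@pytest.fixture(scope="session")
def small_atlas():
    """Desk-size atlas for fast unit tests: 12^3 grid, 8 ROIs, 2 territories/hemisphere."""
    return legnet.build_toy_atlas((12, 12, 12), n_rois=8,
                                  n_territories_per_hemisphere=2, seed=1)


@pytest.fixture(scope="session")
def default_atlas():
    """The package's default atlas: 24^3 grid, 60 ROIs, 3 territories/hemisphere."""
    return legnet.build_toy_atlas((24, 24, 24), n_rois=60,
                                  n_territories_per_hemisphere=3, seed=0)


@pytest.fixture(scope="session")
def small_cohort(small_atlas):
    """12 lesioned subjects on the small atlas."""
    return legnet.generate_cohort(
        12,
        atlas_config=legnet.AtlasConfig(grid_shape=(12, 12, 12), n_rois=8,
                                        n_territories_per_hemisphere=2, seed=1),
        ts_config=legnet.TimeseriesConfig(n_timepoints=60),
        seed=5,
        atlas=small_atlas,
    )


def random_instance(n, hp, seed):
    """A random (X, p, params) triple for layer-level tests."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(np.exp(-1), np.exp(1), (n, n))
    X = (X + X.T) / 2
    p = rng.uniform(0, 1, n)
    params = legnet.init_params(n, hp, seed=seed + 1)
    return X, p, params
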