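import dataclasses

import numpy as np
import pytest

from astrotile import PRESETS, GrowthParams, generate_culture


@pytest.fixture(scope="session")
def small_params() -> GrowthParams:
    """A quick three-cell repulsive culture for unit tests."""
    return dataclasses.replace(
        PRESETS["tiled-DIV15"],
        n_cells=3,
        field_size=(260, 260),
        soma_min_spacing=90.0,
        n_steps=60,
    )


@pytest.fixture(scope="session")
def small_culture(small_params):
    return generate_culture(small_params, 7)


@pytest.fixture(scope="session")
def sparse_culture():
    return generate_culture(PRESETS["sparse-validation"], 11)


@pytest.fixture(scope="session")
def tiled_cultures():
    """Twenty seeded cultures from the repulsive 'tiled-DIV15' preset."""
    return [generate_culture(PRESETS["tiled-DIV15"], seed) for seed in range(1, 21)]


@pytest.fixture()
def rng():
    # fresh, fixed-seed stream per test so outcomes do not depend on
    # which other tests ran first
    return np.random.default_rng(20220409)
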