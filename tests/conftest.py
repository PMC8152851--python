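import numpy as np
import pytest

from glossperm.stimulus_design import (
    build_condition_grid,
    build_gloss_ladder,
    build_selectivity_stimulus_set,
    generate_shape_set,
)


@pytest.fixture(scope="session")
def ladder():
    return build_gloss_ladder(0.029, 0.119, 7, 1.78)


@pytest.fixture(scope="session")
def shape_set():
    return generate_shape_set(session_seed=7)


@pytest.fixture(scope="session")
def shape_ids(shape_set):
    return [s.shape_id for s in shape_set]


@pytest.fixture(scope="session")
def grid(ladder, shape_set):
    return build_condition_grid(ladder, shape_set)


@pytest.fixture(scope="session")
def grid_no_stim(ladder, shape_set):
    return build_condition_grid(ladder, shape_set, include_stimulation_factor=False)


@pytest.fixture(scope="session")
def selectivity_set(ladder, shape_set):
    return build_selectivity_stimulus_set(ladder, shape_set)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
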