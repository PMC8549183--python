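"""Shared fixtures: one small synthetic field of view reused across modules.

Session scope keeps the full render + segmentation to a single run; tests
must not mutate fixture arrays in place.
"""

import numpy as np
import pytest

from erbody import synthetic as syn
from erbody.imgio import PipelineConfig
from erbody.projection import project_volume
from erbody.segmentation import segment_cells, segment_erbodies

# cell size matches the acquisition conditions the pipeline targets
# (~40-50 kpx per epidermal cell at ~0.42 um^2/px)
FIELD = (512, 512)
N_CELLS = 6
SEED = 11


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def mosaic():
    wall, labels = syn.generate_cell_mosaic(N_CELLS, FIELD, SEED)
    return wall, labels


@pytest.fixture(scope="session")
def truth(mosaic):
    wall, labels = mosaic
    return syn.place_erbodies(labels, "wildtype", SEED, wall_image=wall)


@pytest.fixture(scope="session")
def stack(truth):
    return syn.render_zstack(truth, n_slices=4, noise_level=0.01, rng_seed=SEED)


@pytest.fixture(scope="session")
def projection(stack, config):
    return project_volume(stack, config.window_radius, config.smooth_radius)


@pytest.fixture(scope="session")
def cells(projection, config):
    label_map, records = segment_cells(projection, config, image_id="fixture")
    return label_map


@pytest.fixture(scope="session")
def erbody_objects(projection, cells, config):
    return segment_erbodies(projection, cells, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
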