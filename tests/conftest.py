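import numpy as np
import pytest
from scipy.spatial.distance import cdist

from clonoscope.cortex import mouse_s1_model
from clonoscope.render import RenderConfig, render_image
from clonoscope.simulate import SimulationParams, simulate_clones


@pytest.fixture(scope="session")
def s1_model():
    return mouse_s1_model()


@pytest.fixture(scope="session")
def rendered_fixture(s1_model):
    """Zero-noise, bin-centered synthetic slab with >= 50 well-separated clones,
    rendered as a 4-channel 8-bit image; returns (cells, truth, image, model)."""
    params = SimulationParams(
        n_clones=60,
        clone_size_distribution={2: 0.5, 3: 0.5},
        noise_sd=0.0,
        min_cell_separation=20.0,
        seed=11,
    )
    cells, truth = simulate_clones(s1_model, params)
    image = render_image(
        cells, (s1_model.cortical_thickness, s1_model.slab_width), RenderConfig()
    )
    return cells, truth, image, s1_model


def match_detected_to_truth(detected, cells):
    """Map detected cells to simulated cells by nearest centroid.

    Returns the array of matched true cell ids; fails the calling test if the
    matching is not one-to-one.
    """
    d = cdist(detected[["x_um", "y_um"]], cells[["x_um", "y_um"]])
    nearest = d.argmin(axis=1)
    assert len(set(nearest)) == len(detected), "centroid matching is not one-to-one"
    # field-edge blobs are clipped, which can shift the centroid a few um
    assert d.min(axis=1).max() < 4.0, "matched centroids further than 4 um apart"
    return cells.iloc[nearest]["cell_id"].to_numpy()
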