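import numpy as np
import pytest

from cowmon import synthetic as syn
from cowmon.preprocess import make_templates, segment_cow


@pytest.fixture(scope="session")
def scene_small():
    """Half-resolution scene: fast enough for per-test rendering."""
    return syn.SceneParams(shape=(240, 320))


@pytest.fixture(scope="session")
def background_small(scene_small):
    return syn.generate_background(scene_small)


@pytest.fixture(scope="session")
def templates_small(scene_small):
    return make_templates(scene_small)


@pytest.fixture(scope="session")
def clean_cow():
    """Noiseless default-shaped cow."""
    return syn.CowShapeParams(noise_sd=0.0, dropout_rate=0.0)


@pytest.fixture(scope="session")
def clean_segment(scene_small, background_small, clean_cow):
    """Segmented noiseless cow centred in the small scene."""
    frame = syn.generate_cow_frame(scene_small, clean_cow, position_x=0.0)
    seg = segment_cow(frame, background_small)
    assert seg is not None
    return seg


def render_segment(scene, background, cow, position_x=0.0, params=None, geometry=None):
    frame = syn.generate_cow_frame(scene, cow, position_x=position_x)
    return segment_cow(frame, background, params, geometry=geometry)
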