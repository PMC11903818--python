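import numpy as np
import pytest

from irplaque.phantom import (SpectralModel, generate_scene,
                              make_wavenumber_axis, render_pseudo_ihc,
                              StainParams)


@pytest.fixture(scope="session")
def axis16():
    """Compressed 16-channel grid over the full spectral range."""
    return make_wavenumber_axis(1800.0, 948.0, (1800.0 - 948.0) / 15)


@pytest.fixture(scope="session")
def small_scene(axis16):
    """A 128x128 scene with 5 plaques, deterministic."""
    cube, truth = generate_scene(128, 128, 5, SpectralModel(), seed=7,
                                 axis=axis16)
    return cube, truth


@pytest.fixture(scope="session")
def rendered_scene(small_scene):
    cube, truth = small_scene
    img = render_pseudo_ihc(truth, StainParams(seed=11))
    return cube, truth, img
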