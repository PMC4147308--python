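import numpy as np
import pytest

from ajquant import ChannelParams, NoiseParams, SceneSpec, generate_scene


def marker_channels(fm=0.3, fn=0.1, amplitude=100.0, background=20.0):
    """DAPI plus two marker channels with the given planted fractions."""
    return {
        "DAPI": ChannelParams(background_level=5.0, cell_amplitude=50.0,
                              membrane_fraction=0.0, nucleus_fraction=1.0, smooth=True),
        "A488": ChannelParams(background_level=background, cell_amplitude=amplitude,
                              membrane_fraction=fm, nucleus_fraction=fn),
        "A555": ChannelParams(background_level=background, cell_amplitude=amplitude,
                              membrane_fraction=fm, nucleus_fraction=fn),
    }


NOISE_OFF = NoiseParams(poisson=False, gaussian_sd=0.0)


@pytest.fixture(scope="session")
def clean_scene():
    """Small noise-free isolated scene used by several test modules."""
    spec = SceneSpec(n_cells=8, channels=marker_channels(0.4, 0.15),
                     noise=NOISE_OFF, seed=7)
    return generate_scene(spec)


@pytest.fixture(scope="session")
def noisy_scene():
    """Isolated scene with shot + 10%-of-amplitude read noise."""
    spec = SceneSpec(n_cells=12, channels=marker_channels(0.4, 0.15),
                     noise=NoiseParams(poisson=True, gaussian_sd=10.0), seed=13)
    return generate_scene(spec)


def rect_labels(*cells, shape):
    """Label mask from (cell_id, r0, r1, c0, c1) half-open rectangles."""
    lab = np.zeros(shape, dtype=np.int32)
    for cid, r0, r1, c0, c1 in cells:
        lab[r0:r1, c0:c1] = cid
    return lab
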