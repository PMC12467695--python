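import numpy as np
import pytest

from grafangle import NOISELESS, NoiseConfig, make_scene, render_frame

MODERATE_NOISE = NoiseConfig(speckle_scale=0.2, blur_sigma_px=1.0)


@pytest.fixture(scope="session")
def scene70():
    """Standard-plane scene with the phantom's known 70-degree alpha."""
    return make_scene(70.0, 0.0)


@pytest.fixture(scope="session")
def noiseless_frame(scene70):
    """Clean render of the 70-degree scene plus its ground truth."""
    return render_frame(scene70, NOISELESS, seed=0)


@pytest.fixture(scope="session")
def noisy_frame_factory():
    """Factory for seeded moderate-noise frames at a given inclination."""

    def make(seed: int, inclination: float = 0.0, alpha: float = 70.0, **kwargs):
        return render_frame(make_scene(alpha, inclination), MODERATE_NOISE, seed, **kwargs)

    return make
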