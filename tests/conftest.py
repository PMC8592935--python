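import numpy as np
import pytest

from budcut.synthetic import SceneParams, generate_scene


@pytest.fixture(scope="session")
def clean_scene():
    """A noise-free front-lit scene with a moderate tilt."""
    return generate_scene(SceneParams(tilt_delta=12.0, seed=11))


@pytest.fixture(scope="session")
def noisy_scene():
    """Front-lit scene with the standard speck/hole noise regime."""
    return generate_scene(
        SceneParams(tilt_delta=12.0, noise_speck_count=20, noise_hole_count=10, seed=11)
    )


@pytest.fixture(scope="session")
def backlit_scene():
    return generate_scene(
        SceneParams(
            tilt_delta=18.0,
            lighting="back",
            noise_speck_count=20,
            noise_hole_count=10,
            seed=23,
        )
    )


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.astype(bool), b.astype(bool)
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0
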