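import numpy as np
import pytest

from stomatakit.synthetic import SceneParams, generate_scene


@pytest.fixture(scope="session")
def small_params():
    """A fast 256-px field (200 um x 200 um) holding a few stomata."""
    return SceneParams(
        field_width_um=200.0,
        field_height_um=200.0,
        pixels_per_side=256,
        target_density=80.0,
        row_spacing_um=70.0,
        noise_sd=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_scene(small_params):
    return generate_scene(small_params)


@pytest.fixture(scope="session")
def full_noisy_scene():
    """Full 350x-like frame at the study's density with moderate noise."""
    return generate_scene(SceneParams(target_density=80.0, noise_sd=8.0, seed=7))


@pytest.fixture(scope="session")
def full_clean_scene():
    """Noise-free full frame with an even stoma count (46 = round(78.2 x 0.588289))."""
    return generate_scene(SceneParams(target_density=78.2, noise_sd=0.0, seed=11))


def random_blob(rng, side=32, p=0.45):
    """A random connected blob: the largest 8-connected component of a
    Bernoulli field (always nonempty)."""
    from scipy import ndimage

    while True:
        m = rng.random((side, side)) < p
        if not m.any():
            continue
        labels, n = ndimage.label(m, structure=ndimage.generate_binary_structure(2, 2))
        sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
        return labels == (1 + int(np.argmax(sizes)))
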