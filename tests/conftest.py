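import numpy as np
import pytest

from hsdfm import (
    Region,
    SceneSpec,
    WavelengthGrid,
    generate_cube,
    make_tissue_templates,
    normalize_cube,
)


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid.default()


@pytest.fixture(scope="session")
def templates(grid):
    return make_tissue_templates(grid)


@pytest.fixture(scope="session")
def template_map(templates):
    return {t.label: t for t in templates}


def three_stripe_spec(noise_sd=0.0, seed=0, shape=(24, 24)):
    """Three pure stripes: blood / ICT1 / fat."""
    m, n = shape
    h = m // 3
    return SceneSpec(
        shape=shape,
        regions=[
            Region((0, h), (0, n), {"blood": 1.0}),
            Region((h, 2 * h), (0, n), {"ICT1": 1.0}),
            Region((2 * h, m), (0, n), {"fat": 1.0}),
        ],
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture()
def noiseless_scene(templates):
    return generate_cube(three_stripe_spec(), templates)


@pytest.fixture()
def noiseless_cube(noiseless_scene):
    return normalize_cube(
        noiseless_scene.sample, noiseless_scene.dark, noiseless_scene.reference
    )


def brute_spectral_angle(x, mu):
    cos = np.dot(x, mu) / (np.linalg.norm(x) * np.linalg.norm(mu))
    return float(np.arccos(np.clip(cos, 0.0, 1.0)))
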