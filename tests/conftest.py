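import numpy as np
import pytest

import ppixmap as pm


@pytest.fixture(scope="session")
def basis():
    return pm.load_emission_basis()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def simulate_uniform(basis):
    """Factory: simulate one uniform phantom acquisition."""

    def _sim(recipe, size=24, sigma=0.0, seed=0, q_true=2.6):
        scene = pm.PhantomScene.uniform(recipe, (size, size))
        cubes = pm.simulate_acquisition(
            scene,
            pm.IlluminationProfile.for_shape((size, size)),
            pm.IlluminationProfile.for_shape((size, size), angle=-0.2),
            pm.NoiseModel(sigma, seed),
            basis,
            q_true=q_true,
        )
        return scene, cubes

    return _sim


@pytest.fixture(scope="session")
def structured_sim(basis):
    """One noisy structured-phantom acquisition (shared; treated read-only)."""
    size = 96
    scene = pm.make_logo_scene(pm.default_logo_mask((size, size)))
    cubes = pm.simulate_acquisition(
        scene,
        pm.IlluminationProfile.for_shape((size, size)),
        pm.IlluminationProfile.for_shape((size, size), angle=-0.2),
        pm.NoiseModel(0.03, 42),
        basis,
        q_true=2.6,
    )
    c_ls = pm.reconstruct_ls(cubes, basis, q=2.6)
    return scene, c_ls
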