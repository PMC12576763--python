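import numpy as np
import pytest

import sugarnet as sn


@pytest.fixture(scope="session")
def design48():
    return sn.generate_design(3)


@pytest.fixture(scope="session")
def planted_dataset(design48):
    """Two independent-latent modules plus noise genes, fixed seed."""
    specs = [
        sn.PlantedModuleSpec(1, 30, "trait_only", within_module_cor=0.95),
        sn.PlantedModuleSpec(2, 25, "nitrogen", effect_size=6.0, within_module_cor=0.95),
    ]
    X, truth = sn.generate_expression(design48, specs, n_noise_genes=60, seed=11)
    return X, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
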