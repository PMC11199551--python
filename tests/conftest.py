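import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import perturbsig as ps

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


TINY_GENES = 40


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale generator config used across unit tests."""
    return ps.SyntheticConfig(
        n_genes=TINY_GENES, n_cells=2, n_compounds=30, n_replicates=2,
        feature_dim=16, effect_rank=4, noise_sd_basal=0.1,
        noise_sd_pert=0.1, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    matrix, compounds, gt = ps.generate(tiny_config)
    return matrix, compounds, gt


@pytest.fixture(scope="session")
def tiny_pairs(tiny_dataset):
    matrix, _, _ = tiny_dataset
    return ps.prepare_pairs(matrix)


def tiny_model_config(**overrides):
    kw = dict(input_dim=TINY_GENES, feature_dim=16, latent_dim=8,
              enc_hidden=(64, 16), dec_hidden=(16, 32), mol_hidden=(16,),
              batch_size=16, seed=3)
    kw.update(overrides)
    return ps.ModelConfig(**kw)


@pytest.fixture()
def tiny_model():
    return ps.DualVAE(tiny_model_config())
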