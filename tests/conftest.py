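import numpy as np
import pytest

from symzone.phantom import PhantomSpec, generate_phantom
from symzone.sym_net import ModelConfig, build_model

SCALED = dict(volume_shape=(8, 24, 24), spacing_mm=(3.0, 2.5, 2.5),
              lesion_radius_mm=(4.0, 7.0))


@pytest.fixture(scope="session")
def small_model_cfg():
    return ModelConfig(in_channels=5, encoder_channels=(8, 16, 32),
                       decoder_channels=(32, 16, 8), blocks_per_level=2, seed=0)


@pytest.fixture(scope="session")
def small_model(small_model_cfg):
    return build_model(small_model_cfg)


@pytest.fixture(scope="session")
def scaled_case():
    """One scaled phantom with a TZ and a PZ lesion plus a mimic pair."""
    return generate_phantom(PhantomSpec(noise_sigma=0.02, seed=11, **SCALED))


@pytest.fixture(scope="session")
def symmetric_case():
    """Noiseless mimic-only phantom: exactly width-symmetric."""
    return generate_phantom(PhantomSpec(
        n_lesions_tz=0, n_lesions_pz=0, n_symmetric_mimic_pairs=1,
        noise_sigma=0.0, seed=5, **SCALED))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
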