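import numpy as np
import pytest

from sarmdyn.synthetic import SyntheticConfig, generate_ring_complex


@pytest.fixture(scope="session")
def noiseless_cfg() -> SyntheticConfig:
    return SyntheticConfig(seed=1, intensity_noise_cv=0.0)


@pytest.fixture(scope="session")
def ring(noiseless_cfg) -> "StructureModel":
    return generate_ring_complex(noiseless_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_pdb(tmp_path, text, name="toy.pdb"):
    p = tmp_path / name
    p.write_text(text)
    return p
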