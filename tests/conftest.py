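import numpy as np
import pytest

from slidekit.simulate import GeneratorConfig, generate


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down bundle (18 candidate pairs) for fast pipeline tests."""
    return GeneratorConfig(
        seed=42,
        n_focus_genes=3,
        n_focus_partners=3,
        n_druggable_partners=3,
        n_background_genes=3,
        n_cell_lines=120,
        n_patients=300,
        n_reference_patients=150,
        n_drugs=10,
        n_pathways=20,
        planted_pairs=[p for p in GeneratorConfig().planted_pairs[:2]],
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
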