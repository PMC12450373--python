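import numpy as np
import pytest

from plmtune import (
    AminoAcidVocabulary,
    EncoderConfig,
    LoRAConfig,
    SyntheticFamilyConfig,
    build_reference_encoder,
    generate_families,
    inject_lora,
)


@pytest.fixture(scope="session")
def vocab():
    return AminoAcidVocabulary()


@pytest.fixture(scope="session")
def tiny_config():
    return EncoderConfig(
        embedding_dim=16, num_layers=2, num_heads=2,
        max_sequence_length=128, feedforward_dim=32, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_encoder(tiny_config, vocab):
    return build_reference_encoder(tiny_config, vocab)


@pytest.fixture()
def tiny_adapted(tiny_encoder):
    return inject_lora(tiny_encoder, LoRAConfig(rank_r=4, init_seed=3))


@pytest.fixture(scope="session")
def small_families():
    """Ten 8-member families of 60-residue sequences with one conserved block."""
    cfg = SyntheticFamilyConfig(
        n_groups=10,
        members_per_group=8,
        ancestor_length=60,
        conserved_blocks=((10, 10), (40, 8)),
        substitution_rate=0.3,
        seed=11,
    )
    return generate_families(cfg)


@pytest.fixture(scope="session")
def random_vectors():
    rng = np.random.default_rng(5)
    return rng.normal(size=(50, 12))
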