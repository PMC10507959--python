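import numpy as np
import pytest

from molpath.chemio import SmilesTokenizer, generate_fixture_dataset
from molpath.model import ModelConfig, PathwayModel


def tiny_model_config(label_count: int = 5, **overrides) -> ModelConfig:
    """A small architecture for fast unit tests; structural constants
    (threshold, both branches enabled) keep their defaults."""
    args = dict(
        label_count=label_count,
        n_graph_layers=2,
        n_heads=2,
        head_dim=8,
        graph_out_dim=32,
        text_out_dim=32,
        text_embed_dim=8,
        conv_channels=8,
        fusion_channels=4,
        fusion_pool=2,
        fusion_dropout=0.1,
        seed=7,
    )
    args.update(overrides)
    return ModelConfig(**args)


@pytest.fixture(scope="session")
def fixture_dataset():
    return generate_fixture_dataset(20, 5, seed=11, structural_labels=True)


@pytest.fixture(scope="session")
def fitted_tokenizer(fixture_dataset):
    return SmilesTokenizer().fit(fixture_dataset.smiles)


@pytest.fixture()
def tiny_model(fitted_tokenizer):
    return PathwayModel(tiny_model_config(), tokenizer=fitted_tokenizer)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
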