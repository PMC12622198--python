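"""Shared fixtures: vocabularies, toy complexes and a small trained model.

The trained model is session-scoped and deliberately tiny (few complexes,
small pockets, short schedule) so the whole suite stays fast; accuracy-
focused checks live in the acceptance tests, which train at full fixture
scale.
"""

import numpy as np
import pytest

from ligflow.chem_io import DEFAULT_VOCABULARY
from ligflow.equivariant import BackboneConfig
from ligflow.flow import LigandFlowModel, LossWeights, TrainConfig, train
from ligflow.synthetic import FixtureConfig, build_fixture_dataset


@pytest.fixture(scope="session")
def vocab():
    return DEFAULT_VOCABULARY


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_fixture_config():
    return FixtureConfig(n_complexes=8, ligand_size_range=(6, 10),
                         pocket_size_range=(12, 20), seed=2)


@pytest.fixture(scope="session")
def small_records(small_fixture_config):
    return build_fixture_dataset(small_fixture_config)


@pytest.fixture(scope="session")
def desk_config():
    return BackboneConfig.desk_scale()


@pytest.fixture(scope="session")
def untrained_model(vocab, desk_config):
    return LigandFlowModel(vocab, desk_config, seed=3)


@pytest.fixture(scope="session")
def trained_model(vocab, desk_config, small_records):
    """A model briefly trained on the small fixture set (smoke-level fit)."""
    model = LigandFlowModel(vocab, desk_config, seed=0)
    train(small_records, model,
          LossWeights(lambda_affinity=0.1, lambda_confidence=0.1),
          TrainConfig(n_steps=80, batch_size=8, seed=0))
    return model
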