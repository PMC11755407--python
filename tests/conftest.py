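"""Shared fixtures: small planted-rule datasets and fingerprint matrices."""

import numpy as np
import pytest

from pdlscreen import descriptors, models, synthetic


@pytest.fixture(scope="session")
def clean_dataset():
    """Noiseless planted-rule set: the rule is exactly learnable."""
    return synthetic.generate(
        synthetic.SyntheticSpec(n_total=3000, seed=7, label_noise=0.0))


@pytest.fixture(scope="session")
def clean_matrix(clean_dataset):
    return descriptors.assemble_matrix(clean_dataset.records,
                                       families=("morgan",))


@pytest.fixture(scope="session")
def clean_morgan(clean_matrix):
    X = clean_matrix.values.astype(np.uint8)
    fps = {mid: X[i] for i, mid in enumerate(clean_matrix.row_ids)}
    return fps, X


@pytest.fixture(scope="session")
def clean_forest(clean_dataset, clean_matrix):
    return models.train_rf(clean_matrix, clean_dataset.observed_labels(),
                           models.ModelConfig(n_trees=300, seed=11))
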