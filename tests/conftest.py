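"""Shared fixtures: synthetic datasets and trained models reused across
tests to keep the suite inside a reasonable CPU budget."""

import numpy as np
import pytest

from vsdbn import (TrainConfig, build_group_matrix, make_dataset,
                   normalize_columns, train_group)

#: study-scale fixture conditions used wherever trained models are needed
FIXTURE = dict(n_subjects=8, v=100, k1=8, alpha=0.2, noise_sd=0.1, seed=11)
TRAIN = dict(epochs=500, learning_rate=0.01, seed=3)
ARCH = (16, 8, 8)


@pytest.fixture(scope="session")
def dataset02():
    """8 subjects, alpha=0.2: normalized matrices, group matrix, truth."""
    subjects, gt = make_dataset(**FIXTURE)
    subjects = [normalize_columns(s) for s in subjects]
    return subjects, build_group_matrix(subjects), gt


@pytest.fixture(scope="session")
def group_model(dataset02):
    """Stage-1 DBN trained on the alpha=0.2 group matrix."""
    _, grp, _ = dataset02
    return train_group(grp, ARCH, TrainConfig(**TRAIN))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
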