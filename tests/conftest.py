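from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from pcaboot import (
    DataMatrix,
    bandpass_filter,
    build_feature_matrix,
    fit_pca,
    make_epochs,
    standardize,
    synth_feature_matrix,
)
from pcaboot.simulate import SyntheticSpec, synth_eeg_study


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def gaussian_matrix(rng) -> DataMatrix:
    vals = rng.normal(size=(30, 5))
    return DataMatrix(
        values=vals,
        row_ids=[f"r{i}" for i in range(30)],
        col_names=[f"v{j}" for j in range(5)],
    )


@pytest.fixture
def fitted(gaussian_matrix):
    Xs = standardize(gaussian_matrix)
    return Xs, fit_pca(Xs)


@pytest.fixture(scope="session")
def study_matrix():
    """Default-condition 48 x 10 synthetic feature matrix (latent-factor)."""
    return synth_feature_matrix(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def eeg_feature_matrix():
    """48 x 10 matrix built by the full EEG feature pipeline on synthetic
    signals (24 subjects x 2 conditions). Session-scoped: it is the
    slowest fixture."""
    recs = synth_eeg_study(n_subjects=24, seed=11, duration_s=155.0)
    sets = [
        make_epochs(
            bandpass_filter(x, 400.0),
            400.0,
            min_epochs=150,
            subject_id=sid,
            condition=cond,
        )
        for sid, cond, x in recs
    ]
    X, excluded = build_feature_matrix(sets)
    assert excluded == []
    return X
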