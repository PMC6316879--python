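"""Shared fixtures: small exhaustive molecule sets and a tiny trained model.

Everything is generated programmatically and seeded; the session-scoped
trained model keeps the slow work (a short seq1 training run) shared
across the tests that need real weights without requiring convergence.
"""

from __future__ import annotations

import numpy as np
import pytest

from molhetero import datasets, model as model_mod, workflows
from molhetero.representations import enumeration_closed_alphabet


@pytest.fixture(scope="session")
def fixture_molecules():
    """Exhaustive set of molecules with up to 3 heavy atoms over C, N, O."""
    spec = datasets.FixtureSpec(max_heavy_atoms=3, elements=("C", "N", "O"),
                                seed=0)
    return datasets.generate_fixture_molecules(spec)


@pytest.fixture(scope="session")
def alphabet(fixture_molecules):
    return enumeration_closed_alphabet(fixture_molecules)


@pytest.fixture(scope="session")
def maxlen(fixture_molecules):
    return workflows.corpus_maxlen(fixture_molecules, enumerated=True, seed=0)


@pytest.fixture(scope="session")
def tiny_trained_model(fixture_molecules, alphabet, maxlen):
    """A small can2can seq1 model trained briefly on the 3-atom set.

    Trained far past random but not to perfection; suitable for
    split-model identity and decoding-contract tests.
    """
    train_set, test_set = datasets.split_train_test(fixture_molecules, 0.9,
                                                    seed=0)
    pairs = [(m, m) for m in train_set]
    val = [(m, m) for m in test_set]
    cfg = model_mod.HeteroencoderConfig(
        variant="seq1", epochs=150, batch_size=16, initial_lr=0.01,
        lr_patience=40, seed=0)
    handle = model_mod.build_model(cfg, alphabet, alphabet, maxlen)
    trained, history = model_mod.train(handle, pairs, val)
    return trained, history, train_set, test_set


@pytest.fixture(scope="session")
def split_parts(tiny_trained_model):
    trained, _, _, _ = tiny_trained_model
    return model_mod.split_models(trained)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
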