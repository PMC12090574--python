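import numpy as np
import pytest

from crossmeth import (ConditionLabels, EffectSizes, Hyperparameters,
                       SampleMatrix, build_model, fit, generate_compendium)


@pytest.fixture(scope="session")
def tiny_compendium():
    """Small seeded compendium shared by read-only tests."""
    return generate_compendium(S=6, T=4, M=30, seed=101)


@pytest.fixture(scope="session")
def small_hyper():
    return Hyperparameters(hidden_dims=(16,), latent_dim=4, epochs=150,
                           batch_size=32, learning_rate=1e-3,
                           optimizer_epsilon=1e-4)


@pytest.fixture(scope="session")
def trained_small_model(tiny_compendium, small_hyper):
    matrix, labels, _ = tiny_compendium
    model = build_model(small_hyper, matrix.n_probes, labels, seed=7)
    fit(model, matrix, labels, seed=7)
    return model


@pytest.fixture
def toy_matrix():
    values = np.array([[0.2, 0.4, 0.1],
                       [0.6, 0.8, 0.3],
                       [0.5, 0.5, 0.9]])
    matrix = SampleMatrix(values, ["s1", "s2", "s3"], ["p1", "p2", "p3"])
    labels = ConditionLabels(["horse", "horse", "human"],
                             ["liver", "liver", "blood"])
    return matrix, labels
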