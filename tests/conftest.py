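"""Shared fixtures: small trained models and desk-scale pipeline runs."""

import numpy as np
import pytest

from neurosal.bamodel import CNNConfig, build_model, train


@pytest.fixture(scope="session")
def trained_small_model():
    """An 8³ two-block CNN briefly trained on a synthetic intensity→age
    relationship; used wherever a non-degenerate trained model is needed."""
    rng = np.random.default_rng(42)
    X = rng.random((16, 8, 8, 8))
    y = 50.0 + 30.0 * X.mean(axis=(1, 2, 3))
    cfg = CNNConfig(input_size=8, n_blocks=2, filters=(2, 3), conv_kernel=3,
                    dropout_rate=0.0, dropout_blocks=(), dense_sizes=(4,),
                    learning_rate=5e-3, patience=10, max_epochs=15,
                    batch_size=4, seed=3)
    model = build_model(cfg)
    model, _ = train(model, (X[:12], y[:12]), (X[12:], y[12:]), cfg)
    return model, X, y
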