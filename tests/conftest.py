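import numpy as np
import pytest

from hbopipe.synthdata import ExprSimConfig, MeaSimConfig, generate_expression_matrix, generate_mea_recording


@pytest.fixture(scope="session")
def small_recording():
    """A short ground-truthed recording shared across signal/spike tests."""
    cfg = MeaSimConfig(n_channels=4, duration=10.0, rate_hz=1.0, seed=7)
    rec, truth = generate_mea_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def expr_default():
    """A default synthetic expression matrix with its ground truth."""
    cfg = ExprSimConfig(n_genes=2000, seed=11)
    matrix, truth = generate_expression_matrix(cfg)
    return cfg, matrix, truth


@pytest.fixture
def rng():
    return np.random.default_rng(123)
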