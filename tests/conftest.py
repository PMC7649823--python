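import numpy as np
import pytest

from diffge import ExpressionMatrix, SimulationConfig, simulate


@pytest.fixture
def tiny_expr():
    return ExpressionMatrix(
        genes=["g1", "g2", "g3"],
        cells=["c1", "c2"],
        values=np.array([[1.0, 0.0], [2.0, 3.0], [0.0, 0.0]]),
        scale="tpm",
    )


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic dataset shared across tests (read-only)."""
    return simulate(SimulationConfig(seed=7))
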