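import numpy as np
import pytest

from replicount import changepoint as cp


@pytest.fixture(scope="session")
def table_120():
    """Critical-value table for 120-frame traces at 95% confidence."""
    return cp.calibrate_threshold(120, confidence=0.95, n_sim=20_000, seed=11)


@pytest.fixture(scope="session")
def table_long():
    """Table covering the long state-dwell traces of the stoichiometry sweep."""
    lengths = np.array([4, 5, 6, 8, 12, 16, 24, 32, 48, 64, 96, 128, 192, 256, 384, 512, 768, 1024])
    return cp.calibrate_threshold(1024, confidence=0.95, n_sim=10_000, seed=42, lengths=lengths)
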