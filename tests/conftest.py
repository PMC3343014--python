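import numpy as np
import pytest


@pytest.fixture
def rng():
    """Fresh seeded generator per test; deterministic across runs."""
    return np.random.default_rng(20260930)


def three_se(values: np.ndarray) -> float:
    """Three standard errors of the mean of a sample."""
    values = np.asarray(values, dtype=float)
    return 3.0 * values.std(ddof=1) / np.sqrt(values.size)
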