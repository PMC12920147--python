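import numpy as np
import pytest

import somno._autograd as ag
from somno.preprocess import tokenize_recording
from somno.synthetic import SimConfig, simulate_cohort


@pytest.fixture
def fp64():
    """Run the block in float64 (for finite-difference gradient checks)."""
    with ag.use_dtype(np.float64):
        yield


@pytest.fixture(scope="session")
def tiny_cohort():
    """Four patients, 15 minutes each; shared across read-only tests."""
    cfg = SimConfig(n_patients=4, duration_hours=0.25, seed=1)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_token_arrays(tiny_cohort):
    return [tokenize_recording(s.recording) for s in tiny_cohort.recordings]


def finite_difference_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        up = f()
        x[i] = old - eps
        dn = f()
        x[i] = old
        g[i] = (up - dn) / (2 * eps)
    return g
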