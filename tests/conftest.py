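import sys
from pathlib import Path

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(20259)


@pytest.fixture(scope="session")
def small_bundle():
    """One modest simulated experiment shared by read-only tests."""
    from leakmend import simulate

    return simulate.simulate_bundle(
        n_nodes=10, duration=150.0, sampling_rate=100.0, snr=1.0, spread=1.0, seed=314
    )


def random_full_rank(rng, m, n, max_cond=50.0):
    """Random m × n matrix with a bounded condition number."""
    while True:
        Z = rng.normal(size=(m, n))
        s = np.linalg.svd(Z, compute_uv=False)
        if s[0] / s[-1] < max_cond:
            return Z
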