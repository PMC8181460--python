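import os

# the suite is timed on a single CPU; keep BLAS from oversubscribing
os.environ.setdefault("OMP_NUM_THREADS", "1")
os.environ.setdefault("OPENBLAS_NUM_THREADS", "1")
os.environ.setdefault("MKL_NUM_THREADS", "1")

import numpy as np
import pytest

from secblup import (
    build_structural_model,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """One modest dataset with a strong causal signal, reused read-only."""
    model = build_structural_model(1.0, 0.5, 0.5, p=3)
    return simulate_dataset(model, n=150, n_test=40, m=400, seed=11)


@pytest.fixture(scope="session")
def null_dataset():
    """lambda = rho_G = rho_E = 0: focal trait unrelated to secondaries."""
    model = build_structural_model(0.0, 0.0, 0.0, p=3)
    return simulate_dataset(model, n=150, n_test=40, m=400, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)
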