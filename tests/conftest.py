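import os

# single-threaded BLAS: the models here use many small matmuls, where
# thread-pool synchronization costs far more than it saves
for _v in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_v, "1")

import numpy as np
import pytest

from scanstorm import ScanConfig, make_training_crops


@pytest.fixture(scope="session")
def noisy_crops():
    """Small batch of standard simulated training crops (shared)."""
    cfg = ScanConfig(seed=101)
    return make_training_crops(60, cfg, rng=101, noise_sigma=180.0)


@pytest.fixture(scope="session")
def clean_single_crops():
    """Noise-free crops with exactly one accepted emitter each."""
    cfg = ScanConfig(seed=102, shot_noise=False, read_noise=False)
    return make_training_crops(40, cfg, rng=102, n_range=(1, 1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
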