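import os

# pin BLAS threading before numpy loads so training is bit-reproducible
# across machines with different core counts
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from nremlink.sleep_scoring import Hypnogram
from nremlink.synthetic_data import SimConfig


@pytest.fixture(scope="session")
def desk_config() -> SimConfig:
    """Desk-scale generator config: short rests with early REM so every
    modality is exercised quickly."""
    return SimConfig(
        seed=0,
        n_mice=3,
        n_days=3,
        trials_per_day=3,
        rest_duration=1800.0,
        rem_latency_min=240.0,
        trial_duration=60.0,
        include_eeg=False,
    )


@pytest.fixture(scope="session")
def rest_hypnogram(desk_config) -> Hypnogram:
    from nremlink.synthetic_data import simulate_hypnogram

    return simulate_hypnogram(desk_config, desk_config.rest_duration, seed=1)


def make_hypnogram(labels: str, epoch_len: float = 5.0) -> Hypnogram:
    return Hypnogram(np.array(list(labels)), epoch_len=epoch_len)
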