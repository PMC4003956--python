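import numpy as np
import pytest

import tremorkit as tk


@pytest.fixture(scope="session")
def rest_pattern():
    return tk.make_pattern(1)


@pytest.fixture(scope="session")
def line_pattern():
    return tk.make_pattern(3)


@pytest.fixture(scope="session")
def pd_recording(rest_pattern):
    """A 20 s noiseless Parkinsonian-type rest recording."""
    spec = tk.TremorModelSpec("PD", tremor_freq=5.0, tremor_amp=0.003,
                              noise_sd=0.0, seed=11)
    return tk.simulate_recording(rest_pattern, spec, duration=20.0)


def random_rotation(rng) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR of a Gaussian)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
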