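import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numerical_grad(fn, arr: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient of scalar fn w.r.t. arr (float64)."""
    g = np.zeros_like(arr, dtype=np.float64)
    flat = arr.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn()
        flat[i] = orig - eps
        lo = fn()
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g
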