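import numpy as np
import pytest
from hypothesis import settings

from sccnn.stains import HE_DEFAULT, normalize_stain_matrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def he_normalized():
    return normalize_stain_matrix(HE_DEFAULT)


def brute_force_probability_map(centers, shape, d=4.0):
    """O(pixels x centers) reference for the probability-map builder."""
    h, w = shape
    out = np.zeros((h, w))
    if not centers:
        return out
    for r in range(h):
        for c in range(w):
            best_m, best_d2 = None, None
            for m, (cr, cc) in enumerate(centers):
                dr, dc = r - cr, c - cc
                d2 = dr * dr + dc * dc
                if best_d2 is None or d2 < best_d2:
                    best_m, best_d2 = m, d2
            if np.sqrt(best_d2) <= d:
                out[r, c] = 1.0 / (1.0 + best_d2 / 2.0)
    return out
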