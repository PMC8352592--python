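import numpy as np
import pytest

from chromokin import AcquisitionSpec, KineticParams


@pytest.fixture
def gland_acq():
    """Salivary-gland FRAP protocol: 10 pre / 250 post frames at 648 ms."""
    return AcquisitionSpec(n_pre=10, n_post=250, interval=0.648, bleach_depth=0.7)


@pytest.fixture
def s2_acq():
    """S2-cell FRAP protocol: 20 pre / 200 post frames at 70 ms."""
    return AcquisitionSpec(n_pre=20, n_post=200, interval=0.070, bleach_depth=0.7)


@pytest.fixture
def two_component_params():
    return KineticParams(a=0.6, b=0.3, k1=2.0, k2=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_variance(img, radius, mask=None):
    """O(N * |neighborhood|) double-loop local-variance reference."""
    h, w = img.shape
    if mask is None:
        mask = np.ones_like(img, dtype=bool)
    out = np.zeros_like(img, dtype=float)
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            vals = []
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    if di * di + dj * dj > radius * radius:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w and mask[ii, jj]:
                        vals.append(img[ii, jj])
            out[i, j] = np.var(vals)
    return out
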