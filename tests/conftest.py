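import numpy as np
import pytest

from mrenhance import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A 48x48x32 phantom with nested tumor labels, shared across tests."""
    vol, labels = make_phantom(PhantomSpec(shape=(48, 48, 32), seed=7))
    return vol, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def truncate_kspace_1d(line: np.ndarray, keep: int) -> np.ndarray:
    """Reference 1D central k-space truncation used by several oracles.

    Brute-force O(n^2) DFT so it is independent of the package's FFT path.
    """
    n = line.size
    j = np.arange(n)
    dft = np.array([np.sum(line * np.exp(-2j * np.pi * k * j / n)) for k in range(n)])
    shifted = np.fft.fftshift(dft)
    c = n // 2
    lo = c - keep // 2
    mask = np.zeros(n, dtype=bool)
    mask[lo : lo + keep] = True
    shifted[~mask] = 0.0
    back = np.fft.ifftshift(shifted)
    rec = np.array([np.sum(back * np.exp(2j * np.pi * k * j / n)) for k in range(n)]) / n
    return rec.real
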