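"""Shared oracles and fixtures.

The convolution oracle below computes the compound-Poisson pmf from first
principles (explicit Poisson mixture of k-fold convolutions of the
clone-size law), independently of the Panjer recursion it is used to check.
"""

import math

import numpy as np
import pytest

from flucrate.ld_model import clone_size_pmf


def convolution_pmf_oracle(m: float, b: float, nmax: int, j_max: int = 60) -> np.ndarray:
    """p_n = sum_j e^-m m^j / j! * (clone-law^(*j))_n, truncated at j_max clones."""
    n_pows = max(nmax, 1).bit_length()
    severity = np.zeros(nmax + 1)
    for k in range(n_pows):
        if 2**k <= nmax:
            severity[2**k] = clone_size_pmf(b, k)
    pmf = np.zeros(nmax + 1)
    conv = np.zeros(nmax + 1)
    conv[0] = 1.0  # zero clones
    for j in range(j_max + 1):
        pmf += math.exp(-m) * m**j / math.factorial(j) * conv
        conv = np.convolve(conv, severity)[: nmax + 1]
    return pmf


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)
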