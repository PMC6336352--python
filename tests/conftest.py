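import numpy as np
import pytest

from scnclone.hematopoiesis import build_reference_trajectory

#: Published proof-of-principle table: s -> (i, mu, E[T] years).
PRINTED_TABLE = {
    0.005: (240, 2.01e-8, 90.57),
    0.01: (120, 1.00e-8, 46.05),
    0.02: (60, 4.99e-9, 23.41),
    0.03: (40, 3.31e-9, 15.75),
    0.04: (29, 2.47e-9, 11.90),
    0.05: (23, 1.97e-9, 9.57),
    0.1: (11, 9.57e-10, 4.86),
}


@pytest.fixture(scope="session")
def reference_trajectory():
    """Age-calibrated HSC/CMP trajectory shared across takeover tests."""
    return build_reference_trajectory(t_max_years=60.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
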