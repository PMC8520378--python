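from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pacsense import build_basis, make_measurement_matrix, measure
from pacsense.signals import CoefficientVector, as_samples


class IdentityBasis:
    """Trivial orthonormal basis (Psi = I) for closed-form solver checks."""

    name = "identity"
    orthonormal = True

    def __init__(self, N):
        self.N = N

    def matrix(self):
        return np.eye(self.N)

    def real_matrix(self):
        return np.eye(self.N)

    def analyze(self, x):
        return CoefficientVector("identity", as_samples(x))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_sparse_instance(N, M, K, *, basis_name="dct", ensemble="gaussian",
                         seed=0, amp_floor=0.5):
    """Construct a K-sparse recovery instance with known ground truth.

    Coefficient amplitudes are bounded away from zero so the support is
    unambiguous.
    """
    rng = np.random.default_rng(seed)
    basis = build_basis(basis_name, N)
    support = np.sort(rng.choice(N, size=K, replace=False))
    s = np.zeros(N)
    s[support] = (amp_floor + rng.uniform(0.5, 1.5, size=K)) * rng.choice(
        [-1.0, 1.0], size=K
    )
    x = basis.synthesize(s)
    phi = make_measurement_matrix(M, N, ensemble, seed=seed + 1)
    y = measure(phi, x)
    return x, s, support, phi, basis, y
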