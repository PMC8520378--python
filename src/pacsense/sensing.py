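"""Random measurement operators and their incoherence with sparse bases.

Compressed sensing acquires y = Phi x, with Phi an M x N operator whose
rows are incoherent with the columns of the sparse basis Psi.  Three
standard ensembles are provided — i.i.d. Gaussian, symmetric Bernoulli
(+/-1), and uniform row subsampling of the identity — all row-normalized
to unit l2 norm so that coherence values and noise levels are comparable
across ensembles.  Matrix draws and noise draws take separate seeds so an
operator can be held fixed while the noise varies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bases import SparseBasis
from .errors import DimensionError, InvalidShapeError
from .signals import as_samples

ENSEMBLES = ("gaussian", "bernoulli", "subsample")


@dataclass
class MeasurementMatrix:
    """An M x N row-normalized sensing operator Phi."""

    ensemble: str
    M: int
    N: int
    seed: int
    entries: np.ndarray

    def __matmul__(self, x) -> np.ndarray:
        return self.entries @ as_samples(x)


@dataclass
class MeasurementVector:
    """Compressed observations y = Phi x (+ noise), with provenance."""

    values: np.ndarray
    noise_sigma: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("measurement vector contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


def make_measurement_matrix(
    M: int, N: int, ensemble: str = "gaussian", seed: int = 0
) -> MeasurementMatrix:
    """Draw a reproducible M x N sensing matrix from a named ensemble.

    gaussian
        i.i.d. standard normal entries, each row rescaled to unit norm.
    bernoulli
        entries +/- M^(-1/2) with equal probability, rows rescaled to
        unit norm (so entries end up +/- N^(-1/2)).
    subsample
        M distinct rows of the N x N identity, chosen uniformly.
    """
    M, N = int(M), int(N)
    if not (1 <= M <= N):
        raise InvalidShapeError(f"need 1 <= M <= N, got M={M}, N={N}")
    if ensemble not in ENSEMBLES:
        raise InvalidShapeError(
            f"unknown ensemble {ensemble!r}; supported: {', '.join(ENSEMBLES)}"
        )
    rng = np.random.default_rng(seed)
    if ensemble == "gaussian":
        A = rng.standard_normal((M, N))
    elif ensemble == "bernoulli":
        A = rng.choice([-1.0, 1.0], size=(M, N)) / np.sqrt(M)
    else:
        rows = rng.choice(N, size=M, replace=False)
        A = np.eye(N)[rows]
    norms = np.linalg.norm(A, axis=1, keepdims=True)
    A = A / norms
    return MeasurementMatrix(ensemble=ensemble, M=M, N=N, seed=int(seed), entries=A)


def measure(
    phi: MeasurementMatrix,
    x,
    noise_sigma: float = 0.0,
    noise_seed: int = 0,
    label: str = "",
) -> MeasurementVector:
    """Apply y = Phi x + eps with eps ~ N(0, noise_sigma^2) i.i.d., seeded."""
    arr = as_samples(x)
    if arr.size != phi.N:
        raise DimensionError(
            f"signal length {arr.size} does not match operator width {phi.N}"
        )
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0, got {noise_sigma}")
    y = phi.entries @ arr
    if noise_sigma > 0:
        y = y + np.random.default_rng(noise_seed).normal(0.0, noise_sigma, size=phi.M)
    return MeasurementVector(
        values=y,
        noise_sigma=float(noise_sigma),
        provenance={
            "ensemble": phi.ensemble,
            "matrix_seed": phi.seed,
            "noise_seed": int(noise_seed),
            "signal_label": label,
        },
    )


def mutual_coherence(phi: MeasurementMatrix, basis: SparseBasis) -> float:
    """sqrt(N) times the largest |<row of Phi, column of Psi>|, unit-normalized.

    Lies in [1, sqrt(N)]: 1 for maximally incoherent pairs (identity rows
    against the Fourier basis — the classical spike/sinusoid pair), sqrt(N)
    for perfectly aligned ones (identity against identity).
    """
    if phi.N != basis.N:
        raise DimensionError(
            f"operator width {phi.N} does not match basis size {basis.N}"
        )
    psi = basis.matrix()  # columns are unit-norm atoms (orthonormal basis)
    rows = phi.entries  # already unit-norm rows
    inner = np.abs(rows @ psi)
    return float(np.sqrt(phi.N) * inner.max())
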