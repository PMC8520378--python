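"""Orthonormal sparse bases for 1-D compressed sensing.

Five transform families are built in, the ones routinely compared when
profiling the compressibility of ultrasound / photoacoustic RF lines:

``fft``
    Unitary discrete Fourier transform (complex coefficients, N^(-1/2)
    scaling).
``dct``
    Orthonormal DCT-II.
``dst``
    Orthonormal DST-I.
``dht``
    Orthonormal discrete Hartley transform, kernel cas(2*pi*n*k/N)/sqrt(N)
    with cas(t) = cos(t) + sin(t); symmetric and involutory.
``wtransform``
    Wang's generalized discrete W family, kernel
    sqrt(2/N) * sin(pi/4 + 2*pi*(n+a)(k+b)/N) with half-sample shifts
    (a, b) selecting variants I-IV.  Type I (a = b = 0) is the default; its
    kernel algebraically coincides with the Hartley cas kernel, so the
    default W transform and ``dht`` produce identical coefficients — the
    shifted variants II-IV are genuinely distinct.

Every basis is orthonormal, so analysis/synthesis round-trips are exact to
rounding and Parseval's identity holds: ||s||_2 = ||x||_2.

Conventions: coefficients are 0-based with index 0 = DC.  The synthesis
matrix Psi has the atoms as columns, x = Psi @ s; analysis applies Psi^H.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import scipy.fft as sfft

from .errors import DimensionError, InvalidSizeError, UnsupportedBasisError
from .signals import CoefficientVector, Signal1D, as_coefficients, as_samples

BASIS_NAMES = ("fft", "dct", "dst", "dht", "wtransform")

#: (a, b) half-sample shifts of the four Wang W-transform variants.
W_VARIANTS = {1: (0.0, 0.0), 2: (0.5, 0.0), 3: (0.0, 0.5), 4: (0.5, 0.5)}


@lru_cache(maxsize=8)
def _w_analysis_matrix(N: int, variant: int) -> np.ndarray:
    a, b = W_VARIANTS[variant]
    n = np.arange(N)
    return np.sqrt(2.0 / N) * np.sin(np.pi / 4 + 2 * np.pi * np.outer(n + a, n + b) / N)


@lru_cache(maxsize=8)
def _real_fourier_matrix(N: int) -> np.ndarray:
    """Real orthonormal Fourier basis: DC, cos/sin pairs, Nyquist (even N).

    This is the unitary DFT realified under the conjugate-symmetry
    constraint that real signals satisfy; solvers use it so that sparse
    recovery with the ``fft`` basis stays a real-valued problem.
    """
    n = np.arange(N)
    cols = [np.full(N, 1.0 / np.sqrt(N))]
    for k in range(1, (N - 1) // 2 + 1):
        cols.append(np.sqrt(2.0 / N) * np.cos(2 * np.pi * k * n / N))
        cols.append(np.sqrt(2.0 / N) * np.sin(2 * np.pi * k * n / N))
    if N % 2 == 0:
        cols.append(np.cos(np.pi * n) / np.sqrt(N))
    return np.column_stack(cols)


class SparseBasis:
    """A named orthonormal N x N transform with fast analysis/synthesis.

    Do not construct directly; use :func:`build_basis`.
    """

    def __init__(self, name: str, N: int, variant: int = 1):
        self.name = name
        self.N = int(N)
        self.variant = int(variant)
        self.orthonormal = True

    # -- representation ------------------------------------------------

    def __repr__(self) -> str:  # pragma: no cover
        var = f", variant={self.variant}" if self.name == "wtransform" else ""
        return f"SparseBasis({self.name!r}, N={self.N}{var})"

    @property
    def is_complex(self) -> bool:
        return self.name == "fft"

    def _check_signal(self, x: np.ndarray) -> None:
        if x.size != self.N:
            raise DimensionError(
                f"signal length {x.size} does not match basis size {self.N}"
            )

    # -- fast paths ----------------------------------------------------

    def _analyze(self, x: np.ndarray) -> np.ndarray:
        if self.name == "fft":
            return sfft.fft(x, norm="ortho")
        if self.name == "dct":
            return sfft.dct(x, type=2, norm="ortho")
        if self.name == "dst":
            return sfft.dst(x, type=1, norm="ortho")
        if self.name == "dht":
            f = sfft.fft(x, norm="ortho")
            return f.real - f.imag
        return _w_analysis_matrix(self.N, self.variant) @ x

    def _synthesize(self, s: np.ndarray) -> np.ndarray:
        if self.name == "fft":
            x = sfft.ifft(s, norm="ortho")
            return x
        if self.name == "dct":
            return sfft.idct(s, type=2, norm="ortho")
        if self.name == "dst":
            return sfft.idst(s, type=1, norm="ortho")
        if self.name == "dht":
            # involutory: the Hartley transform is its own inverse
            f = sfft.fft(s, norm="ortho")
            return f.real - f.imag
        return _w_analysis_matrix(self.N, self.variant).T @ s

    # -- public API ----------------------------------------------------

    def analyze(self, x) -> CoefficientVector:
        """Coefficients s = Psi^H x of a signal in this basis."""
        arr = as_samples(x)
        self._check_signal(arr)
        return CoefficientVector(self.name, self._analyze(arr))

    def synthesize(self, s) -> Signal1D:
        """Signal x = Psi s from coefficients.

        For the complex Fourier basis the result is the real part of
        Psi s; coefficient vectors produced by :meth:`analyze` on real
        signals are conjugate-symmetric, so nothing is discarded (the
        imaginary remainder is rounding noise, checked to 1e-9).
        """
        if isinstance(s, CoefficientVector) and s.basis_name != self.name:
            raise DimensionError(
                f"coefficients were produced by basis {s.basis_name!r}, "
                f"not {self.name!r}"
            )
        arr = as_coefficients(s)
        if arr.size != self.N:
            raise DimensionError(
                f"coefficient length {arr.size} does not match basis size {self.N}"
            )
        x = self._synthesize(arr)
        if np.iscomplexobj(x):
            x = x.real
        return Signal1D(x)

    def matrix(self) -> np.ndarray:
        """Explicit synthesis matrix Psi (atoms as columns); complex for fft.

        Cached per (name, N, variant); treat the returned array as
        read-only.
        """
        return _synthesis_matrix(self.name, self.N, self.variant)

    def real_matrix(self) -> np.ndarray:
        """Real orthonormal synthesis matrix used by the recovery solvers.

        Identical to :meth:`matrix` for the four real bases; for ``fft`` it
        is the realified Fourier basis (conjugate symmetry imposed).
        """
        if self.name == "fft":
            return _real_fourier_matrix(self.N)
        return self.matrix()


@lru_cache(maxsize=8)
def _synthesis_matrix(name: str, N: int, variant: int) -> np.ndarray:
    n = np.arange(N)
    if name == "fft":
        return np.exp(2j * np.pi * np.outer(n, n) / N) / np.sqrt(N)
    if name == "wtransform":
        return _w_analysis_matrix(N, variant).T
    if name == "dct":
        return sfft.idct(np.eye(N), type=2, norm="ortho", axis=0)
    if name == "dst":
        return sfft.idst(np.eye(N), type=1, norm="ortho", axis=0)
    # dht: symmetric cas kernel
    arg = 2 * np.pi * np.outer(n, n) / N
    return (np.cos(arg) + np.sin(arg)) / np.sqrt(N)


def build_basis(name: str, N: int, variant: int = 1) -> SparseBasis:
    """Construct one of the built-in orthonormal bases.

    Parameters
    ----------
    name
        One of ``fft``, ``dct``, ``dst``, ``dht``, ``wtransform``
        (case-insensitive; ``w`` is accepted for ``wtransform``).
    N
        Transform size, at least 2.
    variant
        W-transform type, 1-4 (ignored by the other bases).
    """
    key = str(name).strip().lower()
    if key == "w":
        key = "wtransform"
    if key not in BASIS_NAMES:
        raise UnsupportedBasisError(
            f"unknown basis {name!r}; supported: {', '.join(BASIS_NAMES)}"
        )
    if int(N) < 2:
        raise InvalidSizeError(f"basis size must be >= 2, got {N}")
    if key == "wtransform" and variant not in W_VARIANTS:
        raise UnsupportedBasisError(
            f"W-transform variant must be one of {sorted(W_VARIANTS)}, got {variant}"
        )
    return SparseBasis(key, int(N), variant)


def analyze(basis: SparseBasis, x) -> CoefficientVector:
    """Functional alias for :meth:`SparseBasis.analyze`."""
    return basis.analyze(x)


def synthesize(basis: SparseBasis, s) -> Signal1D:
    """Functional alias for :meth:`SparseBasis.synthesize`."""
    return basis.synthesize(s)
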