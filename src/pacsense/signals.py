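"""Light containers for 1-D signals and transform coefficients.

The numerical payload is always a plain :class:`numpy.ndarray`; the
dataclasses only carry provenance (a label, the basis name) and enforce
finiteness.  Every public function in pacsense also accepts a bare array
wherever a :class:`Signal1D` is expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError


@dataclass
class Signal1D:
    """A real-valued sampled signal of length N (arbitrary amplitude units)."""

    samples: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 1:
            raise DimensionError("signal must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"signal {self.label!r} contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def N(self) -> int:
        return self.samples.size


@dataclass
class CoefficientVector:
    """Transform coefficients s with x = Psi s; complex for the Fourier basis."""

    basis_name: str
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if not np.iscomplexobj(values):
            values = values.astype(float)
        self.values = values.ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coefficient vector contains non-finite values")

    def __len__(self) -> int:
        return self.values.size

    def magnitudes(self) -> np.ndarray:
        """|s| — modulus for complex coefficients, absolute value otherwise."""
        return np.abs(self.values)


def as_samples(x) -> np.ndarray:
    """Coerce a Signal1D or array-like to a float 1-D array."""
    if isinstance(x, Signal1D):
        return x.samples
    return np.asarray(x, dtype=float).ravel()


def as_coefficients(s) -> np.ndarray:
    """Coerce a CoefficientVector or array-like to a 1-D array."""
    if isinstance(s, CoefficientVector):
        return s.values
    arr = np.asarray(s)
    return arr.ravel()
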