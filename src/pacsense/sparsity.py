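"""Threshold-based sparsity measurement and basis-comparison profiling.

A transform coefficient vector is declared effectively sparse by hard
thresholding: coefficients whose magnitude is strictly smaller than a
threshold are regarded as 0, and the number of survivors is the sparsity
count.  In the default *relative* mode the effective threshold is
``c * max|s|``, so counts are invariant to signal scaling and a single
grid of c values (0.01, 0.05, 0.1 by default) is meaningful across
signals of very different lengths and amplitudes.

Profiling the same signal across several bases yields a threshold-by-basis
table of counts — the standard way to pick the basis in which a signal
family is most compressible before designing a compressed-sensing
acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .bases import BASIS_NAMES, SparseBasis, build_basis
from .errors import InvalidKError, InvalidThresholdError
from .signals import CoefficientVector, Signal1D, as_coefficients, as_samples

DEFAULT_THRESHOLDS = (0.01, 0.05, 0.1)

THRESHOLD_MODES = ("relative", "absolute")


def _effective_threshold(mags: np.ndarray, c: float, mode: str) -> float:
    if not np.isscalar(c) or not float(c) > 0:
        raise InvalidThresholdError(f"threshold must be > 0, got {c!r}")
    if mode not in THRESHOLD_MODES:
        raise InvalidThresholdError(f"unknown threshold mode {mode!r}")
    if mode == "relative":
        peak = mags.max() if mags.size else 0.0
        return float(c) * float(peak)
    return float(c)


def sparsity_count(s, c: float, mode: str = "relative") -> int:
    """Number of coefficients whose magnitude survives the threshold.

    Magnitudes strictly smaller than the effective threshold are zeroed;
    equality survives.  An all-zero vector yields 0 in either mode.
    """
    mags = np.abs(as_coefficients(s))
    thr = _effective_threshold(mags, c, mode)
    return int(np.count_nonzero(mags >= thr) if thr > 0 else np.count_nonzero(mags))


def hard_threshold(s, c: float, mode: str = "relative") -> CoefficientVector:
    """Set sub-threshold coefficients to exactly 0 (idempotent)."""
    name = s.basis_name if isinstance(s, CoefficientVector) else "unknown"
    values = as_coefficients(s).copy()
    mags = np.abs(values)
    thr = _effective_threshold(mags, c, mode)
    if thr > 0:
        values[mags < thr] = 0
    return CoefficientVector(name, values)


@dataclass
class SparsityProfile:
    """Threshold-by-basis table of nonzero-coefficient counts.

    ``table`` is a DataFrame indexed by threshold c with one column per
    basis, mirroring the printed layout of a basis-comparison table.
    """

    signal_label: str
    table: pd.DataFrame
    threshold_mode: str = "relative"

    @property
    def thresholds(self) -> list[float]:
        return [float(c) for c in self.table.index]

    @property
    def bases(self) -> list[str]:
        return list(self.table.columns)

    def count(self, c: float, basis: str) -> int:
        return int(self.table.loc[c, basis])


def sparsity_profile(
    x,
    bases=BASIS_NAMES,
    thresholds=DEFAULT_THRESHOLDS,
    mode: str = "relative",
    label: str | None = None,
) -> SparsityProfile:
    """Decompose a signal in several bases and count survivors per threshold.

    Returns one count per (threshold, basis) pair, deterministic for a
    given signal.
    """
    arr = as_samples(x)
    if label is None:
        label = x.label if isinstance(x, Signal1D) else ""
    names = []
    columns = {}
    for b in bases:
        basis = b if isinstance(b, SparseBasis) else build_basis(b, arr.size)
        coeffs = basis.analyze(arr)
        names.append(basis.name)
        columns[basis.name] = [sparsity_count(coeffs, c, mode) for c in thresholds]
    table = pd.DataFrame(columns, index=pd.Index([float(c) for c in thresholds], name="c"))
    return SparsityProfile(signal_label=label, table=table, threshold_mode=mode)


@dataclass
class KSparseApprox:
    """Best K-term approximation of a coefficient vector."""

    K: int
    retained_support: np.ndarray
    coefficients: CoefficientVector
    relative_l2_error: float
    meta: dict = field(default_factory=dict)


def best_k_approx(s, K: int, basis: SparseBasis | None = None) -> KSparseApprox:
    """Keep the K largest-magnitude coefficients (ties: lowest index wins).

    The reported relative l2 error is that of the synthesized K-term
    signal against the full signal; for an orthonormal basis this equals
    the coefficient-domain error, so the basis argument is optional and
    only changes which domain the bookkeeping happens in.
    """
    values = as_coefficients(s)
    name = s.basis_name if isinstance(s, CoefficientVector) else "unknown"
    N = values.size
    if not (0 <= int(K) <= N):
        raise InvalidKError(f"K must lie in [0, {N}], got {K}")
    K = int(K)
    mags = np.abs(values)
    # stable sort on (-magnitude, index): ties broken by lowest index
    order = np.argsort(-mags, kind="stable")
    support = np.sort(order[:K])
    approx = np.zeros_like(values)
    approx[support] = values[support]
    total = float(np.linalg.norm(values))
    if total == 0.0:
        err = 0.0
    else:
        err = float(np.linalg.norm(values - approx) / total)
    return KSparseApprox(
        K=K,
        retained_support=support,
        coefficients=CoefficientVector(name, approx),
        relative_l2_error=err,
    )


def best_k_error_exhaustive(s, K: int) -> float:
    """Brute-force minimal relative l2 error over all K-subsets (small N).

    Independent oracle for :func:`best_k_approx`; cost grows as C(N, K).
    """
    values = as_coefficients(s)
    N = values.size
    total = float(np.linalg.norm(values))
    if total == 0.0:
        return 0.0
    best = np.inf
    for subset in combinations(range(N), int(K)):
        approx = np.zeros_like(values)
        idx = list(subset)
        approx[idx] = values[idx]
        best = min(best, float(np.linalg.norm(values - approx)))
    return best / total
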