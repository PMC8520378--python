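"""Sparse recovery: greedy l0 (OMP), convex l1 (ISTA/FISTA), exact l0 oracle.

The acquisition model is y = Phi x + eps with x = Psi s sparse in an
orthonormal basis.  Recovery estimates s from the underdetermined system
y = A s, A = Phi Psi, either by the greedy l0 heuristic (orthogonal
matching pursuit), by the l1 relaxation

    min_s  0.5 * ||y - A s||_2^2 + lam * ||s||_1

solved with proximal gradient iterations (ISTA, or its accelerated
monotone-FISTA variant), or — for tiny instances only — by exhaustive
least squares over all candidate supports, which serves as the exact
l0 oracle in tests.

All solvers work in a real coordinate system: for the complex Fourier
basis, A uses the realified Fourier basis (conjugate symmetry imposed),
so supports and coefficient estimates are real-valued throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.linalg import lstsq

from .bases import SparseBasis
from .errors import (
    DimensionError,
    InfeasibleKError,
    InstanceTooLargeError,
    InvalidPenaltyError,
)
from .sensing import MeasurementMatrix, MeasurementVector
from .signals import CoefficientVector, Signal1D, as_samples


@dataclass
class ReconstructionResult:
    """Output of a sparse solver.

    ``s_hat`` holds coefficients in the basis's native domain (complex for
    fft); ``support`` indexes the solver's real coordinate system;
    ``residual_l2`` is ||y - Phi x_hat||_2.
    """

    x_hat: Signal1D
    s_hat: CoefficientVector
    support: np.ndarray
    residual_l2: float
    iterations: int
    objective_trace: np.ndarray
    solver: str
    converged: bool = True
    info: dict = field(default_factory=dict)


@dataclass
class RecoveryMetrics:
    """Quality of a reconstruction against known ground truth."""

    relative_l2_error: float
    psnr_db: float
    support_precision: float
    support_recall: float
    absolute_l2_error: float
    zero_truth: bool = False


def _system(phi: MeasurementMatrix, basis: SparseBasis) -> np.ndarray:
    if phi.N != basis.N:
        raise DimensionError(
            f"operator width {phi.N} does not match basis size {basis.N}"
        )
    return phi.entries @ basis.real_matrix()


def _values(y) -> np.ndarray:
    if isinstance(y, MeasurementVector):
        return y.values
    return np.asarray(y, dtype=float).ravel()


def _finish(
    phi: MeasurementMatrix,
    basis: SparseBasis,
    s_real: np.ndarray,
    y: np.ndarray,
    support: np.ndarray,
    trace,
    solver: str,
    converged: bool = True,
    info: dict | None = None,
) -> ReconstructionResult:
    x_hat = Signal1D(basis.real_matrix() @ s_real, label=f"{solver} reconstruction")
    residual = float(np.linalg.norm(y - phi.entries @ x_hat.samples))
    return ReconstructionResult(
        x_hat=x_hat,
        s_hat=basis.analyze(x_hat),
        support=np.asarray(sorted(int(i) for i in support), dtype=int),
        residual_l2=residual,
        iterations=len(trace),
        objective_trace=np.asarray(trace, dtype=float),
        solver=solver,
        converged=converged,
        info=info or {},
    )


# ---------------------------------------------------------------------------
# Orthogonal matching pursuit
# ---------------------------------------------------------------------------

def omp(
    y,
    phi: MeasurementMatrix,
    basis: SparseBasis,
    K: int,
    tol: float = 0.0,
) -> ReconstructionResult:
    """Greedy l0 solver: pick the atom most correlated with the residual,
    least-squares refit on the accumulated support, repeat.

    Stops after K atoms or when the residual norm drops to ``tol``.
    Correlation ties are broken toward the lowest index, making the solver
    deterministic.
    """
    yv = _values(y)
    K = int(K)
    if not (1 <= K <= phi.M):
        raise InfeasibleKError(f"need 1 <= K <= M={phi.M}, got K={K}")
    A = _system(phi, basis)
    if yv.size != phi.M:
        raise DimensionError(f"y has length {yv.size}, expected M={phi.M}")

    support: list[int] = []
    coef = np.zeros(0)
    r = yv.copy()
    trace = []
    for _ in range(K):
        corr = np.abs(A.T @ r)
        corr[support] = -1.0  # never re-select
        j = int(np.argmax(corr))  # first maximum -> lowest index on ties
        support.append(j)
        coef, *_ = lstsq(A[:, support], yv)
        r = yv - A[:, support] @ coef
        trace.append(float(np.linalg.norm(r)))
        if trace[-1] <= tol:
            break
    s = np.zeros(A.shape[1])
    s[support] = coef
    return _finish(phi, basis, s, yv, support, trace, "omp")


# ---------------------------------------------------------------------------
# Proximal gradient (ISTA / monotone FISTA)
# ---------------------------------------------------------------------------

def _soft(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _spectral_norm_sq(A: np.ndarray, iters: int = 100) -> float:
    """lambda_max(A^T A) by power iteration, deterministic start."""
    rng = np.random.default_rng(12345)
    v = rng.standard_normal(A.shape[1])
    v /= np.linalg.norm(v)
    lam = 1.0
    for _ in range(iters):
        w = A.T @ (A @ v)
        lam = float(np.linalg.norm(w))
        if lam == 0.0:
            return 0.0
        v = w / lam
    return lam


def ista_l1(
    y,
    phi: MeasurementMatrix,
    basis: SparseBasis,
    lam: float,
    max_iter: int = 2000,
    tol: float = 1e-10,
    accelerated: bool = False,
    debias: bool = False,
    support_atol: float = 1e-12,
) -> ReconstructionResult:
    """l1-penalized least squares by proximal gradient.

    Step size is 1/L with L the power-method estimate of the squared
    spectral norm of A = Phi Psi plus a 5% safety margin, which guarantees
    descent without a line search.  ``accelerated`` switches to the
    monotone-FISTA variant (momentum, but the objective is kept
    non-increasing by falling back to the previous iterate whenever the
    momentum step would increase it).  Iterations stop when the relative
    objective change falls below ``tol``; hitting ``max_iter`` first flags
    the result as not converged rather than raising.

    ``debias=True`` re-fits the nonzero coefficients by least squares on
    the recovered support, removing the soft-threshold shrinkage bias.
    """
    if not lam > 0:
        raise InvalidPenaltyError(f"l1 penalty must be > 0, got {lam}")
    yv = _values(y)
    A = _system(phi, basis)
    if yv.size != phi.M:
        raise DimensionError(f"y has length {yv.size}, expected M={phi.M}")

    L = 1.05 * _spectral_norm_sq(A, iters=100)
    step = 1.0 / L if L > 0 else 1.0

    def objective(s: np.ndarray) -> float:
        r = yv - A @ s
        return 0.5 * float(r @ r) + lam * float(np.abs(s).sum())

    s = np.zeros(A.shape[1])
    y_pt = s.copy()  # momentum point (FISTA); equals s for plain ISTA
    t = 1.0
    trace = [objective(s)]
    converged = False
    for _ in range(int(max_iter)):
        if accelerated:
            # monotone FISTA: momentum step, but never accept an increase
            grad = A.T @ (A @ y_pt - yv)
            z = _soft(y_pt - step * grad, lam * step)
            fz = objective(z)
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            accepted = fz <= trace[-1]
            s_new = z if accepted else s
            f_new = fz if accepted else trace[-1]
            y_pt = (
                s_new
                + (t / t_next) * (z - s_new)
                + ((t - 1.0) / t_next) * (s_new - s)
            )
            t = t_next
        else:
            grad = A.T @ (A @ s - yv)
            s_new = _soft(s - step * grad, lam * step)
            f_new = objective(s_new)
            accepted = True
        trace.append(min(f_new, trace[-1]))
        f_prev = trace[-2]
        s = s_new
        if accepted and abs(f_prev - f_new) <= tol * max(1.0, abs(f_prev)):
            converged = True
            break

    support = np.flatnonzero(np.abs(s) > support_atol)
    if debias and support.size:
        coef, *_ = lstsq(A[:, support], yv)
        s = np.zeros_like(s)
        s[support] = coef
    solver = "fista" if accelerated else "ista"
    return _finish(
        phi, basis, s, yv, support, trace, solver,
        converged=converged, info={"lam": float(lam), "step": step, "debias": debias},
    )


# ---------------------------------------------------------------------------
# Exhaustive l0 oracle (small instances only)
# ---------------------------------------------------------------------------

def exhaustive_l0(
    y, phi: MeasurementMatrix, basis: SparseBasis, K: int
) -> ReconstructionResult:
    """Exact l0 minimizer by least squares over every support of size <= K.

    Guarded to N <= 16 and K <= 3; the combinatorial cost makes anything
    larger pointless.  This is the oracle the greedy solver is tested
    against.
    """
    yv = _values(y)
    K = int(K)
    N = basis.N
    if N > 16 or K > 3:
        raise InstanceTooLargeError(
            f"exhaustive search limited to N <= 16, K <= 3 (got N={N}, K={K})"
        )
    if K < 0:
        raise InfeasibleKError(f"K must be >= 0, got {K}")
    A = _system(phi, basis)

    best_support: tuple[int, ...] = ()
    best_coef = np.zeros(0)
    best_res = float(np.linalg.norm(yv))
    if K > 0:
        for subset in combinations(range(N), min(K, N)):
            cols = A[:, list(subset)]
            coef, *_ = lstsq(cols, yv)
            res = float(np.linalg.norm(yv - cols @ coef))
            if res < best_res - 1e-12 * max(1.0, best_res):
                best_res = res
                best_support = subset
                best_coef = coef
    s = np.zeros(N)
    if best_support:
        s[list(best_support)] = best_coef
    return _finish(phi, basis, s, yv, best_support, [best_res], "exhaustive_l0")


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(x_true, result: ReconstructionResult, support_true=None) -> RecoveryMetrics:
    """Relative l2 error, PSNR (peak = max|x_true|) and support metrics.

    A zero true signal makes the relative error undefined; the absolute
    l2 error is reported instead and ``zero_truth`` is flagged.
    """
    xt = as_samples(x_true)
    xh = result.x_hat.samples
    if xt.size != xh.size:
        raise DimensionError(f"length mismatch: {xt.size} vs {xh.size}")
    diff = xt - xh
    abs_err = float(np.linalg.norm(diff))
    norm_true = float(np.linalg.norm(xt))
    zero_truth = norm_true == 0.0
    rel_err = abs_err if zero_truth else abs_err / norm_true

    peak = float(np.abs(xt).max()) if xt.size else 0.0
    rmse = abs_err / np.sqrt(xt.size)
    if rmse == 0.0 or peak == 0.0:
        psnr = np.inf if rmse == 0.0 else -np.inf
    else:
        psnr = 20.0 * np.log10(peak / rmse)

    if support_true is None:
        precision = recall = np.nan
    else:
        truth = set(int(i) for i in np.asarray(support_true).ravel())
        found = set(int(i) for i in result.support)
        hit = len(truth & found)
        precision = (hit / len(found)) if found else (1.0 if not truth else 0.0)
        recall = (hit / len(truth)) if truth else 1.0
    return RecoveryMetrics(
        relative_l2_error=float(rel_err),
        psnr_db=float(psnr),
        support_precision=float(precision),
        support_recall=float(recall),
        absolute_l2_error=abs_err,
        zero_truth=zero_truth,
    )
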