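"""Sparse solvers: OMP against the exhaustive l0 oracle, ISTA/FISTA
descent and closed-form checks, and the evaluation metrics."""

import numpy as np
import pytest

from pacsense import (
    build_basis,
    evaluate,
    exhaustive_l0,
    ista_l1,
    make_measurement_matrix,
    measure,
    omp,
)
from pacsense.errors import (
    InfeasibleKError,
    InstanceTooLargeError,
    InvalidPenaltyError,
)
from pacsense.recover import ReconstructionResult
from pacsense.signals import Signal1D

from conftest import make_sparse_instance


class TestOMP:
    def test_single_atom_recovered_exactly(self):
        x, s, support, phi, basis, y = make_sparse_instance(
            20, 20, 1, ensemble="subsample", seed=0)
        result = omp(y, phi, basis, K=1)
        assert result.residual_l2 < 1e-10
        assert list(result.support) == list(support)
        assert np.allclose(result.x_hat.samples, x.samples, atol=1e-10)

    def test_k5_instance_recovered_to_machine_precision(self):
        x, s, support, phi, basis, y = make_sparse_instance(300, 100, 5, seed=7)
        result = omp(y, phi, basis, K=5)
        metrics = evaluate(x, result, support_true=support)
        assert metrics.relative_l2_error < 1e-6
        assert metrics.support_precision == 1.0
        assert metrics.support_recall == 1.0

    def test_never_beats_the_l0_oracle(self):
        for seed in range(20):
            x, s, support, phi, basis, y = make_sparse_instance(
                10, 6, 2, seed=seed)
            greedy = omp(y, phi, basis, K=2)
            oracle = exhaustive_l0(y, phi, basis, K=2)
            assert oracle.residual_l2 <= greedy.residual_l2 + 1e-10

    def test_matches_oracle_when_optimum_is_unique(self):
        hits = 0
        for seed in range(20):
            x, s, support, phi, basis, y = make_sparse_instance(
                10, 6, 2, seed=seed)
            oracle = exhaustive_l0(y, phi, basis, K=2)
            if oracle.residual_l2 < 1e-9:  # exact, hence unique a.s.
                greedy = omp(y, phi, basis, K=2)
                if greedy.residual_l2 < 1e-9:
                    assert list(greedy.support) == list(oracle.support)
                    hits += 1
        assert hits > 0

    def test_infeasible_k_rejected(self):
        _, _, _, phi, basis, y = make_sparse_instance(20, 5, 2, seed=1)
        with pytest.raises(InfeasibleKError):
            omp(y, phi, basis, K=6)

    def test_tolerance_stops_early(self):
        x, s, support, phi, basis, y = make_sparse_instance(50, 25, 3, seed=3)
        result = omp(y, phi, basis, K=10, tol=1e-8)
        assert result.iterations <= 4  # stops once the residual vanishes
        assert result.residual_l2 <= 1e-8


class TestISTA:
    def test_huge_penalty_returns_zero(self):
        _, _, _, phi, basis, y = make_sparse_instance(40, 20, 3, seed=2)
        A = phi.entries @ basis.real_matrix()
        lam = 2.0 * np.abs(A.T @ y.values).max()
        result = ista_l1(y, phi, basis, lam=lam, max_iter=50)
        assert np.all(result.x_hat.samples == 0)
        assert result.support.size == 0

    def test_identity_system_equals_soft_thresholding(self, rng):
        """Phi = I, Psi = I: the minimizer is the elementwise
        soft-threshold of y at lam (the proximal operator itself)."""
        from conftest import IdentityBasis
        N = 30
        phi = make_measurement_matrix(N, N, "subsample", seed=0)
        phi.entries = np.eye(N)
        y = rng.standard_normal(N)
        lam = 0.3
        result = ista_l1(y, phi, IdentityBasis(N), lam=lam, max_iter=500,
                         tol=1e-14)
        expected = np.sign(y) * np.maximum(np.abs(y) - lam, 0.0)
        assert np.allclose(result.x_hat.samples, expected, atol=1e-8)

    @pytest.mark.parametrize("accelerated", (False, True))
    def test_objective_trace_non_increasing(self, accelerated):
        x, s, support, phi, basis, y = make_sparse_instance(100, 40, 5, seed=5)
        result = ista_l1(y, phi, basis, lam=1e-3, max_iter=400,
                         accelerated=accelerated)
        trace = result.objective_trace
        assert np.all(np.diff(trace) <= 1e-12)

    @pytest.mark.parametrize("accelerated", (False, True))
    def test_debiased_solution_matches_truth(self, accelerated):
        x, s, support, phi, basis, y = make_sparse_instance(300, 100, 5, seed=7)
        result = ista_l1(y, phi, basis, lam=1e-3, max_iter=6000, tol=1e-13,
                         accelerated=accelerated, debias=True)
        metrics = evaluate(x, result, support_true=support)
        assert metrics.relative_l2_error < 1e-3

    def test_invalid_penalty_rejected(self):
        _, _, _, phi, basis, y = make_sparse_instance(20, 10, 2, seed=0)
        with pytest.raises(InvalidPenaltyError):
            ista_l1(y, phi, basis, lam=0.0)

    def test_non_convergence_flags_instead_of_raising(self):
        _, _, _, phi, basis, y = make_sparse_instance(60, 30, 4, seed=9)
        result = ista_l1(y, phi, basis, lam=1e-8, max_iter=3, tol=1e-16)
        assert isinstance(result, ReconstructionResult)
        assert not result.converged


class TestExhaustiveL0:
    def test_k_zero_gives_zero_solution(self):
        _, _, _, phi, basis, y = make_sparse_instance(10, 6, 2, seed=4)
        result = exhaustive_l0(y, phi, basis, K=0)
        assert np.all(result.x_hat.samples == 0)
        assert result.residual_l2 == pytest.approx(np.linalg.norm(y.values))

    def test_matches_independent_enumeration(self):
        """Cross-check against a second, independently coded enumeration."""
        from itertools import combinations
        x, s, support, phi, basis, y = make_sparse_instance(8, 5, 2, seed=6)
        result = exhaustive_l0(y, phi, basis, K=2)
        A = phi.entries @ basis.real_matrix()
        best = np.inf
        for sub in combinations(range(8), 2):
            cols = A[:, sub]
            coef = np.linalg.pinv(cols) @ y.values
            best = min(best, np.linalg.norm(y.values - cols @ coef))
        assert result.residual_l2 == pytest.approx(best, abs=1e-9)

    def test_size_guard(self):
        _, _, _, phi, basis, y = make_sparse_instance(20, 10, 2, seed=0)
        with pytest.raises(InstanceTooLargeError):
            exhaustive_l0(y, phi, basis, K=2)  # N = 20 > 16


class TestEvaluate:
    def _result_for(self, x_hat, support=()):
        x_hat = Signal1D(np.asarray(x_hat, dtype=float))
        basis = build_basis("dct", len(x_hat))
        return ReconstructionResult(
            x_hat=x_hat, s_hat=basis.analyze(x_hat),
            support=np.asarray(support, dtype=int), residual_l2=0.0,
            iterations=0, objective_trace=np.array([]), solver="omp")

    def test_perfect_recovery(self):
        x = [1.0, -2.0, 0.0, 3.0]
        m = evaluate(x, self._result_for(x, (0, 1, 3)), support_true=(0, 1, 3))
        assert m.relative_l2_error == 0.0
        assert m.psnr_db == np.inf
        assert m.support_precision == 1.0 and m.support_recall == 1.0

    def test_zero_estimate_vs_nonzero_truth(self):
        m = evaluate([1.0, 0.0, 2.0], self._result_for([0.0, 0.0, 0.0]),
                     support_true=(0, 2))
        assert m.relative_l2_error == pytest.approx(1.0)
        assert m.support_recall == 0.0

    def test_hand_computed_psnr(self):
        # truth (2, 0, -2, 0), estimate (1, 0, -2, 0):
        # peak = 2, rmse = 1/2, psnr = 20 log10(4) = 12.0412 dB
        m = evaluate([2.0, 0.0, -2.0, 0.0],
                     self._result_for([1.0, 0.0, -2.0, 0.0]))
        assert m.psnr_db == pytest.approx(20 * np.log10(4.0), abs=1e-9)

    def test_zero_truth_reports_absolute_error(self):
        m = evaluate([0.0, 0.0], self._result_for([0.3, 0.4]))
        assert m.zero_truth
        assert m.relative_l2_error == pytest.approx(0.5)


def test_noise_degrades_recovery_continuously():
    """Relative error grows smoothly with the noise level; no blow-up at
    small sigma."""
    x, s, support, phi, basis, _ = make_sparse_instance(100, 50, 4, seed=11)
    errs = []
    for sigma in (0.0, 1e-4, 1e-3, 1e-2):
        y = measure(phi, x, noise_sigma=sigma, noise_seed=42)
        result = omp(y, phi, basis, K=4)
        errs.append(evaluate(x, result).relative_l2_error)
    assert errs[0] < 1e-9
    # error scales roughly linearly with sigma; within two orders here
    assert errs[1] < 1e-2 and errs[2] < 1e-1 and errs[3] < 1.0
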