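"""Recovering a sparse signal from 3x fewer measurements.

Constructs a signal that is 5-sparse in the DCT domain (N = 300),
compresses it to M = 100 Gaussian measurements and recovers it with the
greedy l0 solver (OMP) and the accelerated l1 solver (FISTA + debias).
"""

import numpy as np

from pacsense import (
    build_basis, evaluate, ista_l1, make_measurement_matrix, measure, omp,
)

N, M, K = 300, 100, 5
rng = np.random.default_rng(7)
basis = build_basis("dct", N)
support = np.sort(rng.choice(N, size=K, replace=False))
s = np.zeros(N)
s[support] = rng.uniform(1.0, 2.0, K) * rng.choice([-1.0, 1.0], K)
x = basis.synthesize(s)

phi = make_measurement_matrix(M, N, "gaussian", seed=7)
y = measure(phi, x)
print(f"truth: {K}-sparse in DCT, support {[int(i) for i in support]}; "
      f"M/N = {M}/{N} measurements")

for name, result in [
    ("omp", omp(y, phi, basis, K=K)),
    ("fista", ista_l1(y, phi, basis, lam=1e-3, max_iter=6000, tol=1e-13,
                      accelerated=True, debias=True)),
]:
    m = evaluate(x, result, support_true=support)
    print(f"{name:>6}: relative l2 error = {m.relative_l2_error:.2e}, "
          f"support recall = {m.support_recall:.2f}, "
          f"iterations = {result.iterations}")
print()
print("Both solvers identify the exact support; errors at machine precision")
print("mean the 3x undersampled acquisition lost no information.")
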