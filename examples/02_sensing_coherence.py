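"""How incoherent is a measurement ensemble with a sparse basis?

Builds the three measurement ensembles at M = 16, N = 64 and prints
their mutual coherence with the DCT and Fourier bases.  Coherence lies
in [1, sqrt(N)]; values near 1 mean each measurement spreads its energy
over all basis atoms, the regime in which few measurements suffice.
"""

import numpy as np

from pacsense import build_basis, make_measurement_matrix, mutual_coherence

M, N = 16, 64
print(f"mutual coherence, M={M}, N={N} (range [1, sqrt(N)] = [1, {np.sqrt(N):.0f}])\n")
print(f"{'ensemble':<10} {'vs dct':>8} {'vs fft':>8}")
for ensemble in ("gaussian", "bernoulli", "subsample"):
    phi = make_measurement_matrix(M, N, ensemble, seed=0)
    mus = [mutual_coherence(phi, build_basis(b, N)) for b in ("dct", "fft")]
    print(f"{ensemble:<10} {mus[0]:>8.3f} {mus[1]:>8.3f}")
print()
print("Identity-row subsampling is maximally incoherent with the Fourier")
print("basis (the classical spike/sinusoid pair, coherence exactly 1) but")
print("useless for signals sparse in the spike domain itself.")
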