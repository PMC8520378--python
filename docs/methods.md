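# Methods

## Scope

pacsense implements the compressed-sensing workflow for 1-D
ultrasound/photoacoustic RF signals: sparse decomposition in five
orthonormal bases, threshold-based compressibility profiling, random
measurement with coherence diagnostics, greedy and l1 sparse recovery,
and a synthetic phantom generator that emulates a laser-triggered
contrast-enhancement experiment. Wet-lab aspects of such experiments
(nanoparticle chemistry, cell targeting, instrumentation) are out of
scope; the phantom reproduces the *design* of a three-arm imaging
experiment and its qualitative signal behaviour, not any physical
magnitudes.

## Sparse bases

All five bases are orthonormal N×N transforms, so analysis/synthesis
round-trips and Parseval's identity are exact contracts (tested to 1e-9
relative) rather than approximations:

* **fft** — unitary DFT, `N^(-1/2)` scaling, complex coefficients.
* **dct** — DCT-II with orthonormal scaling (`scipy.fft.dct(type=2,
  norm="ortho")`).
* **dst** — DST-I with orthonormal scaling; self-inverse.
* **dht** — discrete Hartley transform, kernel `cas(2πnk/N)/√N` with
  `cas t = cos t + sin t`; symmetric and involutory. Computed from the
  FFT via `Re − Im`.
* **wtransform** — Wang's generalized discrete W family, kernel
  `√(2/N)·sin(π/4 + 2π(n+a)(k+b)/N)` with half-sample shifts
  `(a, b) ∈ {0, ½}²` selecting types I–IV. Orthogonality of all four
  types is verified in the test suite. Type I is the default; since
  `√2·sin(π/4 + t) = cas t`, type I coincides *exactly* with the
  Hartley kernel, so the default W column of a sparsity profile
  duplicates the DHT column. The shifted types II–IV are genuinely
  distinct and available through the `variant` parameter. The family
  is applied as an explicit (cached) matrix; no fast factorization is
  implemented because profiling at N ≤ 1841 is matmul-cheap.

These specific variants were chosen because the transform *families*
admit many normalizations; the orthonormal members make the round-trip
and Parseval contracts exact and keep one thresholding rule meaningful
across bases. Coefficients are 0-based with index 0 = DC.

Where a solver needs a real coordinate system for the complex Fourier
basis, the realified orthonormal Fourier basis is used (DC column,
`cos/sin` pairs, Nyquist column for even N) — the result of imposing the
conjugate-symmetry constraint that real signals satisfy. Supports
reported by solvers refer to this real system; coefficient estimates are
also reported in the basis's native domain.

## Threshold sparsity and profiling

A coefficient is "regarded as zero" when its magnitude is *strictly*
below the effective threshold; equality survives. The default mode is
**relative**: the effective threshold is `c · max|s|`, which makes
counts invariant to signal scaling and lets one grid of c values
(defaults 0.01, 0.05, 0.1) apply to signals of any length or amplitude.
Absolute thresholds are available for completeness. Magnitude means
modulus for complex coefficients — sign and phase carry no energy.

Profiles are threshold × basis tables of surviving counts, serialized as
CSV with threshold rows and basis columns, the layout in which such
basis comparisons are conventionally printed. Structural guarantees
(counts ≤ N, non-increasing in c, scale invariance) are tested; the
qualitative pattern that smooth signals with nonzero boundary values
need the *most* DST coefficients (a sine basis forces zeros at the
boundaries, producing Gibbs-like decay) is asserted on the packaged
fixtures, which were selected to display it.

Best-K approximation keeps the K largest magnitudes, ties broken toward
the lower index; for orthonormal bases this greedy choice is optimal,
which the suite cross-checks against exhaustive subset search at N ≤ 12.

## Sensing

Three standard ensembles: i.i.d. Gaussian, symmetric Bernoulli ±1, and
uniform row-subsampling of the identity. All matrices are
**row-normalized** to unit l2 norm so that mutual-coherence values and
noise levels are comparable across ensembles (column normalization would
leave subsampled-identity and Gaussian rows at different scales).
Matrix seed and noise seed are separate inputs so an operator can be
held fixed while noise varies. The only noise model is additive i.i.d.
Gaussian — the minimal standard choice.

Mutual coherence is `√N · max |⟨row, atom⟩|` over all pairs, both
unit-normalized; it is bounded in `[1, √N]` (lower bound: the coefficient
vector of a unit row in an orthonormal basis has unit norm, so its
largest entry is at least `N^(-1/2)`), and the spike/Fourier pair attains
exactly 1.

## Recovery solvers

* **OMP** selects the atom of `A = ΦΨ` most correlated with the current
  residual (ties → lowest index, for determinism), refits by least
  squares on the accumulated support, and stops at K atoms or residual
  ≤ tol.
* **ISTA/FISTA** minimizes `½‖y − As‖² + λ‖s‖₁` by proximal gradient
  with fixed step `1/L`, where `L` is a 100-iteration power-method
  estimate of `‖A‖²` inflated by 5% — guaranteeing descent without line
  search. The accelerated path is the *monotone* FISTA variant: the
  momentum step is taken, but an iterate that would increase the
  objective is rejected in favour of the previous one, so the objective
  trace is non-increasing for both solvers (a tested invariant; plain
  FISTA is famously non-monotone). Iterations stop when the relative
  objective change drops below `tol`; exhausting `max_iter` flags the
  result as unconverged instead of raising. An optional **debias** step
  refits the recovered support by least squares, removing the
  soft-threshold shrinkage bias; it is off by default in the library
  function and on in the demo pipeline, where support identification
  rather than the biased l1 minimizer is the point.
* **exhaustive_l0** enumerates every support of size ≤ K (guarded to
  N ≤ 16, K ≤ 3) with a per-support least-squares fit. It is the exact
  l0 oracle that the greedy solver is tested against — oracle residual
  ≤ OMP residual on every instance.

Practical λ guidance: with unit-normalized rows and O(1) coefficient
amplitudes, λ around `1e-3` converges in a few hundred FISTA iterations;
much smaller λ approaches basis pursuit but slows plain ISTA roughly in
proportion (the demo instance needs ~6500 ISTA iterations at λ = 1e-4
versus ~700 at 1e-3, with identical debiased solutions).

Evaluation reports relative l2 error, PSNR with peak `max|x_true|`, and
support precision/recall. A zero true signal makes relative error
undefined; the absolute error is reported with a flag.

## Phantom generator

**Test signals.** Three kinds, all deterministic per seed:

* `harmonic_mixture` (default) — the compressible input for
  sparsity/recovery studies. Component frequencies are locked to the
  DCT-II grid: each component is a quadrature pair of two adjacent DCT
  atoms with a seeded mixing angle playing the role of phase, so a
  noiseless mixture of k components is *exactly* 2k-sparse in the DCT
  domain. This is a deliberate design choice: an off-grid sinusoid
  spreads energy across the entire DCT spectrum, and the generator's
  contract — best-2k approximation error below 1e-6 — would be
  unattainable. The cost is realism: real RF signals are only
  approximately sparse, so exact-recovery results on this generator are
  a best case. Optional white noise at a configurable SNR (dB) restores
  approximate sparsity. Canonical lengths are N = 1841 and N = 300.
* `chirp_plus_spikes` — a linear chirp with seeded impulses, sparse in
  no single basis; useful as a stress input.
* `piecewise_smooth` — seeded quadratic segments with jumps.

**A-lines.** Each optical absorber is a uniformly heated sphere whose
pressure signature is the classical N-shaped bipolar pulse:
`A·(t − t₀)/τ` for `|t − t₀| ≤ τ`, with arrival `t₀ = depth/c` and
half-duration `τ = radius/c`. Units: depth and radius in mm, time in µs,
sound speed 1.5 mm/µs (soft tissue). Defaults: three absorbers at
9/15/22.5 mm with radii 0.45/0.6/0.75 mm and amplitudes 1.0/0.8/0.6,
sampled at 40 samples/µs over 20 µs (N = 800), additive Gaussian noise
σ = 0.02 (≈ 2% of the strongest echo). A pulse extending outside the
time window is an error rather than a silent truncation. The model
deliberately omits acoustic propagation, transducer response and fluence:
it provides superposition-exact, desk-computable ground truth.

**Contrast experiment.** Three arms: `AP_GNP` (targeted phase-change
agent; post-irradiation amplitudes scaled by the enhancement factor,
default 3), `NP` (blank particles, factor forced to 1) and `water` (no
absorbers; acquisition noise only). Pre and post acquisitions take
independent noise draws derived from one seed via seed-sequence
spawning. Noiseless, the post/pre l2 ratio for the targeted arm equals
the factor exactly (amplitude scaling is linear), and across seeds mean
post-irradiation energy orders AP_GNP > NP > water — the qualitative
outcome such an experiment is designed to show. The factor is an
explicit knob, not a claim about any physical system; enhancement in
real phase-change agents is also a change of pulse shape, not a pure
gain.

## Packaged fixtures

Two harmonic-mixture test signals (N = 1841, components 8, SNR 25 dB,
seed 1; N = 300, components 4, SNR 25 dB, seed 3) and one three-arm
contrast set (default phantom, factor 3, seed 11), all as delimited text
with their generator settings in header comments;
`scripts/make_fixtures.py` regenerates them bit-exactly. The fixture
seeds were chosen so the packaged signals display the DST-dominant
profile pattern documented above; roughly half of harmonic-mixture seeds
do at N = 1841.

## Numerical choices and problem sizes

* Tolerances: 1e-9 relative for round-trip/Parseval, 1e-10 for
  fast-path-vs-matrix agreement, 1e-12 slack on objective monotonicity.
* Ties: lowest index wins everywhere (best-K retention, OMP atom
  selection, exhaustive-search support comparison), making every solver
  deterministic.
* Test problem sizes: transform exactness at N ∈ {8, 64, 300, 1841}
  with 100 random signals each; oracle-dominance over 200 instances at
  N ≤ 12; the recovery phase transition at N = 128, K = 4,
  M ∈ {8, 16, 32, 64} with 50 seeds per M; the canonical recovery
  instance K = 5, N = 300, M = 100. These sizes exercise every code
  path at full numerical precision while keeping the whole suite in the
  seconds range.

## Known limitations

* Strictly 1-D: images are handled only by applying the pipeline
  per A-line; no 2-D transforms, beamforming or TV regularization.
* No structured operators (partial Fourier, Toeplitz) and no RIP
  estimation beyond mutual coherence.
* The W-transform default duplicates the Hartley basis (kernel
  identity); choose variants 2–4 for a genuinely different W basis.
* The phantom's exact sparsity and noise-free enhancement are idealized;
  passing tests demonstrate correctness of the algorithms, not
  performance on measured RF data, whose compressibility must be
  profiled before trusting undersampled acquisition.
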