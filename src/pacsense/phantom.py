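"""Synthetic signal generators: compressible test signals and photoacoustic
A-lines with a laser-triggered contrast-enhancement experiment.

Two families of inputs are produced:

* Generic 1-D *test signals* for transform-compressibility profiling
  (``harmonic_mixture``, ``chirp_plus_spikes``, ``piecewise_smooth``),
  at the canonical lengths N = 1841 and N = 300.

* Photoacoustic *A-lines*: each optical absorber in a tissue-mimicking
  gel phantom emits the classical N-shaped bipolar pressure pulse of a
  uniformly heated sphere, amplitude * (t - t0)/tau inside
  |t - t0| <= tau, with arrival time t0 = depth / sound_speed and
  half-duration tau = radius / sound_speed.  A-lines are superpositions
  of these pulses plus additive Gaussian noise.

The contrast experiment emulates a three-arm phase-change study: a
targeted phase-change contrast agent (``AP_GNP``) whose echo amplitude is
multiplied by an enhancement factor after laser irradiation, a blank
nanoparticle arm (``NP``) with no enhancement, and a ``water`` arm that
contains no absorbers at all (noise only).

On the harmonic mixture: component frequencies are locked to the DCT-II
grid — each component is a quadrature pair of two adjacent DCT atoms with
a seeded mixing angle standing in for phase — so a noiseless mixture of
``components`` sinusoids is exactly 2*components-sparse in the DCT
domain.  Off-grid frequencies would leak energy across the whole
spectrum and the signal would only be approximately compressible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft as sfft

from .errors import InvalidFactorError, OutOfWindowError, UnsupportedKindError
from .signals import Signal1D

TEST_SIGNAL_KINDS = ("harmonic_mixture", "chirp_plus_spikes", "piecewise_smooth")
CONTRAST_GROUPS = ("AP_GNP", "NP", "water")

#: canonical test-signal lengths used throughout the package
DEFAULT_LENGTHS = (1841, 300)


# ---------------------------------------------------------------------------
# Generic compressible test signals
# ---------------------------------------------------------------------------

@dataclass
class TestSignalConfig:
    """Recipe for a generic compressible test signal.

    snr_db = None means noiseless; otherwise white Gaussian noise is added
    at the requested signal-to-noise ratio.
    """

    N: int = 300
    kind: str = "harmonic_mixture"
    components: int = 3
    snr_db: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 8:
            raise ValueError(f"N must be >= 8, got {self.N}")
        if self.components < 1:
            raise ValueError(f"components must be >= 1, got {self.components}")
        if self.kind not in TEST_SIGNAL_KINDS:
            raise UnsupportedKindError(
                f"unknown kind {self.kind!r}; supported: {', '.join(TEST_SIGNAL_KINDS)}"
            )


def _add_noise(x: np.ndarray, snr_db: float | None, rng: np.random.Generator) -> np.ndarray:
    if snr_db is None or np.isinf(snr_db):
        return x
    power = float(np.mean(x**2))
    if power == 0.0:
        return x
    sigma = np.sqrt(power / 10.0 ** (snr_db / 10.0))
    return x + rng.normal(0.0, sigma, size=x.size)


def generate_test_signal(config: TestSignalConfig) -> Signal1D:
    """Deterministic (per seed) synthetic signal of the configured kind."""
    rng = np.random.default_rng(config.seed)
    N, k = config.N, config.components

    if config.kind == "harmonic_mixture":
        # seeded DCT-grid frequencies; quadrature pair per component
        coeffs = np.zeros(N)
        freqs = rng.choice(np.arange(1, max(N // 4, k * 2 + 2), 2), size=k, replace=False)
        for f in freqs:
            amp = rng.uniform(0.5, 1.5)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            coeffs[f] += amp * np.cos(phase)
            coeffs[f + 1] += amp * np.sin(phase)
        x = sfft.idct(coeffs, type=2, norm="ortho")
    elif config.kind == "chirp_plus_spikes":
        n = np.arange(N) / N
        x = np.sin(2.0 * np.pi * (N / 16.0) * n * (0.25 + 0.75 * n))  # linear chirp
        pos = rng.choice(N, size=k, replace=False)
        x[pos] += rng.uniform(1.0, 3.0, size=k) * rng.choice([-1.0, 1.0], size=k)
    else:  # piecewise_smooth
        edges = np.sort(rng.choice(np.arange(1, N), size=k, replace=False))
        x = np.empty(N)
        for lo, hi in zip(np.r_[0, edges], np.r_[edges, N]):
            if hi <= lo:
                continue
            t = np.linspace(-1.0, 1.0, hi - lo)
            a, b, c = rng.uniform(-1.0, 1.0, size=3)
            x[lo:hi] = a + b * t + c * t**2
    x = _add_noise(x, config.snr_db, rng)
    return Signal1D(x, label=f"{config.kind}(N={N}, seed={config.seed})")


# ---------------------------------------------------------------------------
# Photoacoustic A-lines
# ---------------------------------------------------------------------------

@dataclass
class PhantomConfig:
    """Geometry and acquisition settings for a synthetic A-line.

    Depths and radii in mm, time in microseconds, sound speed in mm/us
    (1.5 mm/us ~ soft tissue).
    """

    absorber_positions: tuple[float, ...] = (9.0, 15.0, 22.5)
    absorber_radii: tuple[float, ...] = (0.45, 0.6, 0.75)
    absorber_amplitudes: tuple[float, ...] = (1.0, 0.8, 0.6)
    sound_speed: float = 1.5
    sampling_rate: float = 40.0  # samples per microsecond
    duration: float = 20.0  # microseconds
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.absorber_positions, dtype=float)
        rad = np.asarray(self.absorber_radii, dtype=float)
        amp = np.asarray(self.absorber_amplitudes, dtype=float)
        if not (pos.size == rad.size == amp.size):
            raise ValueError("positions, radii and amplitudes must have equal length")
        if np.any(rad <= 0):
            raise ValueError("absorber radii must be > 0")
        if np.any(amp < 0):
            raise ValueError("absorber amplitudes must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        max_depth = self.duration * self.sound_speed
        if np.any(pos < 0) or np.any(pos > max_depth):
            raise OutOfWindowError(
                f"absorber depths must lie in [0, {max_depth}] mm"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def generate_pa_aline(config: PhantomConfig) -> Signal1D:
    """Superpose one N-wave per absorber on the time grid, add noise."""
    t = np.arange(config.n_samples) / config.sampling_rate
    x = np.zeros_like(t)
    for depth, radius, amp in zip(
        config.absorber_positions, config.absorber_radii, config.absorber_amplitudes
    ):
        t0 = depth / config.sound_speed
        tau = radius / config.sound_speed
        if t0 - tau < 0 or t0 + tau > config.duration:
            raise OutOfWindowError(
                f"N-wave at t0={t0:.3f} us (tau={tau:.3f}) exceeds the "
                f"[0, {config.duration}] us window"
            )
        mask = np.abs(t - t0) <= tau
        x[mask] += amp * (t[mask] - t0) / tau
    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        x = x + rng.normal(0.0, config.noise_sigma, size=x.size)
    return Signal1D(x, label=f"pa_aline(seed={config.seed})")


# ---------------------------------------------------------------------------
# Three-group contrast-enhancement experiment
# ---------------------------------------------------------------------------

@dataclass
class ContrastExperiment:
    """Pre/post-irradiation A-line pair for one experimental arm."""

    group: str
    pre: Signal1D
    post: Signal1D
    enhancement_factor: float
    config: PhantomConfig | None = field(default=None, repr=False)


def simulate_contrast_experiment(
    config: PhantomConfig,
    group: str = "AP_GNP",
    enhancement_factor: float = 3.0,
    seed: int | None = None,
) -> ContrastExperiment:
    """Simulate one arm of the laser-irradiation experiment.

    ``AP_GNP``: post-irradiation absorber amplitudes are scaled by the
    enhancement factor (the phase-change echo boost).  ``NP``: no
    enhancement (factor forced to 1).  ``water``: no absorbers at all in
    either acquisition.  Pre and post acquisitions use independent noise
    draws derived from ``seed`` (defaults to ``config.seed``).
    """
    if group not in CONTRAST_GROUPS:
        raise InvalidFactorError(
            f"unknown group {group!r}; supported: {', '.join(CONTRAST_GROUPS)}"
        )
    if enhancement_factor < 1:
        raise InvalidFactorError(
            f"enhancement factor must be >= 1, got {enhancement_factor}"
        )
    base_seed = config.seed if seed is None else int(seed)
    pre_seed, post_seed = (
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(base_seed).spawn(2)
    )

    amps = np.asarray(config.absorber_amplitudes, dtype=float)
    if group == "water":
        amps = np.zeros_like(amps)
        factor = 1.0
    elif group == "NP":
        factor = 1.0
    else:
        factor = float(enhancement_factor)

    pre_cfg = replace(config, absorber_amplitudes=tuple(amps), seed=pre_seed)
    post_cfg = replace(config, absorber_amplitudes=tuple(amps * factor), seed=post_seed)
    pre = generate_pa_aline(pre_cfg)
    post = generate_pa_aline(post_cfg)
    pre.label = f"{group} pre-irradiation"
    post.label = f"{group} post-irradiation"
    return ContrastExperiment(
        group=group, pre=pre, post=post, enhancement_factor=factor, config=config
    )
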