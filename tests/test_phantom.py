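"""Synthetic generators: determinism, DCT compressibility of the harmonic
mixture, N-wave geometry, and the three-arm contrast experiment."""

import numpy as np
import pytest

from pacsense import (
    PhantomConfig,
    best_k_approx,
    build_basis,
    generate_pa_aline,
    generate_test_signal,
    simulate_contrast_experiment,
    sparsity_count,
)
from pacsense.phantom import TestSignalConfig as SignalCfg
from pacsense.errors import (
    InvalidFactorError,
    OutOfWindowError,
    UnsupportedKindError,
)
from pacsense.phantom import TEST_SIGNAL_KINDS


class TestTestSignals:
    @pytest.mark.parametrize("kind", TEST_SIGNAL_KINDS)
    def test_same_seed_same_signal(self, kind):
        cfg = SignalCfg(N=256, kind=kind, components=4, snr_db=20.0, seed=9)
        a = generate_test_signal(cfg)
        b = generate_test_signal(cfg)
        assert np.array_equal(a.samples, b.samples)

    def test_noiseless_harmonic_mixture_is_exactly_sparse_in_dct(self):
        """Each component occupies two DCT atoms, so best-2k error ~ 0."""
        for comps in (1, 3, 6):
            cfg = SignalCfg(N=300, components=comps, seed=4)
            x = generate_test_signal(cfg)
            s = build_basis("dct", 300).analyze(x)
            assert best_k_approx(s, 2 * comps).relative_l2_error < 1e-6

    def test_harmonic_mixture_profiles_as_compressible(self):
        cfg = SignalCfg(N=300, components=3, seed=0)
        s = build_basis("dct", 300).analyze(generate_test_signal(cfg))
        assert sparsity_count(s, 0.1) <= 12

    def test_best_tenth_error_small_for_noiseless_mixture(self):
        cfg = SignalCfg(N=1841, components=8, seed=1)
        x = generate_test_signal(cfg)
        s = build_basis("dct", 1841).analyze(x)
        assert best_k_approx(s, 1841 // 10).relative_l2_error < 0.1

    def test_canonical_lengths_build_and_profile(self):
        from pacsense import sparsity_profile
        for N in (1841, 300):
            x = generate_test_signal(SignalCfg(N=N, seed=0))
            table = sparsity_profile(x).table
            assert (table.values <= N).all()

    def test_unknown_kind_rejected(self):
        with pytest.raises(UnsupportedKindError):
            SignalCfg(N=64, kind="wavelet_train")


class TestALine:
    def test_no_absorbers_no_noise_is_silent(self):
        cfg = PhantomConfig(absorber_positions=(), absorber_radii=(),
                            absorber_amplitudes=(), noise_sigma=0.0)
        assert np.all(generate_pa_aline(cfg).samples == 0)

    def test_nwave_arrival_time_from_depth(self):
        """An absorber at 15 mm with c = 1.5 mm/us echoes at t0 = 10 us."""
        cfg = PhantomConfig(absorber_positions=(15.0,), absorber_radii=(0.6,),
                            absorber_amplitudes=(1.0,), noise_sigma=0.0)
        x = generate_pa_aline(cfg)
        t = np.arange(cfg.n_samples) / cfg.sampling_rate
        nonzero = t[x.samples != 0]
        tau = 0.6 / 1.5
        assert nonzero.min() >= 10.0 - tau - 1e-9
        assert nonzero.max() <= 10.0 + tau + 1e-9
        # bipolar N shape: rising through zero at t0
        i0 = np.argmin(np.abs(t - 10.0))
        assert abs(x.samples[i0]) < 1e-9
        assert x.samples[i0 - 3] < 0 < x.samples[i0 + 3]

    def test_superposition_of_absorbers_is_linear(self):
        one = PhantomConfig(absorber_positions=(9.0,), absorber_radii=(0.45,),
                            absorber_amplitudes=(1.0,), noise_sigma=0.0)
        two = PhantomConfig(absorber_positions=(22.5,), absorber_radii=(0.75,),
                            absorber_amplitudes=(0.6,), noise_sigma=0.0)
        both = PhantomConfig(absorber_positions=(9.0, 22.5),
                             absorber_radii=(0.45, 0.75),
                             absorber_amplitudes=(1.0, 0.6), noise_sigma=0.0)
        lhs = generate_pa_aline(both).samples
        rhs = generate_pa_aline(one).samples + generate_pa_aline(two).samples
        assert np.allclose(lhs, rhs, atol=1e-14)

    def test_absorber_outside_window_rejected(self):
        with pytest.raises(OutOfWindowError):
            generate_pa_aline(PhantomConfig(
                absorber_positions=(29.9,), absorber_radii=(0.6,),
                absorber_amplitudes=(1.0,)))  # pulse tail exceeds 20 us

    def test_noise_is_seeded(self):
        cfg = PhantomConfig(noise_sigma=0.05, seed=21)
        assert np.array_equal(generate_pa_aline(cfg).samples,
                              generate_pa_aline(cfg).samples)


class TestContrastExperiment:
    def _noiseless(self):
        return PhantomConfig(noise_sigma=0.0)

    def test_enhancement_scales_the_l2_norm_exactly(self):
        exp = simulate_contrast_experiment(self._noiseless(), "AP_GNP",
                                           enhancement_factor=3.0, seed=1)
        ratio = np.linalg.norm(exp.post.samples) / np.linalg.norm(exp.pre.samples)
        assert ratio == pytest.approx(3.0, abs=1e-12)

    def test_blank_particles_show_no_enhancement(self):
        exp = simulate_contrast_experiment(self._noiseless(), "NP",
                                           enhancement_factor=3.0, seed=1)
        assert exp.enhancement_factor == 1.0
        assert np.allclose(exp.pre.samples, exp.post.samples, atol=1e-14)

    def test_np_pre_post_differ_only_by_noise(self):
        cfg = PhantomConfig(noise_sigma=0.02)
        exp = simulate_contrast_experiment(cfg, "NP", seed=2)
        diff = exp.post.samples - exp.pre.samples
        # difference of two independent N(0, sigma^2) draws
        assert np.std(diff) == pytest.approx(np.sqrt(2) * 0.02, rel=0.15)

    def test_water_arm_is_noise_only(self):
        cfg = PhantomConfig(noise_sigma=0.02)
        energies = []
        for seed in range(100):
            exp = simulate_contrast_experiment(cfg, "water", seed=seed)
            energies.append(np.mean(exp.post.samples ** 2))
        # mean energy ~ sigma^2 across seeds
        assert np.mean(energies) == pytest.approx(0.02 ** 2, rel=0.1)

    def test_group_energy_ordering(self):
        """Post-irradiation energy: targeted agent > blank > water."""
        cfg = PhantomConfig(noise_sigma=0.02)
        means = {}
        for group in ("AP_GNP", "NP", "water"):
            e = [np.mean(simulate_contrast_experiment(
                cfg, group, enhancement_factor=3.0, seed=s).post.samples ** 2)
                for s in range(30)]
            means[group] = np.mean(e)
        assert means["AP_GNP"] > means["NP"] > means["water"]

    def test_invalid_factor_and_group_rejected(self):
        with pytest.raises(InvalidFactorError):
            simulate_contrast_experiment(self._noiseless(), "AP_GNP",
                                         enhancement_factor=0.5)
        with pytest.raises(InvalidFactorError):
            simulate_contrast_experiment(self._noiseless(), "saline")
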