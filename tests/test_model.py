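"""Wave-shape, IMT-parameter, noise and cohort-generator behavior."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pulsesst as ps
from pulsesst.model import DegenerateShapeError, _jitter_shape


class TestWaveShape:
    def test_pure_cosine(self):
        s = ps.make_wave_shape([0.0, 1.0], [0.0])
        assert s.delta == 0.0
        assert s.energy == pytest.approx(0.5)
        assert ps.eval_wave_shape(s, 0.0) == pytest.approx(1.0)
        sn = ps.make_wave_shape([0.0, 1.0], [0.0], normalize=True)
        assert sn.energy == pytest.approx(1.0)

    def test_dominance_ratio_equal_harmonics(self):
        s = ps.make_wave_shape([0.0, 1.0, 1.0], [0.0, 0.0])
        assert s.delta == pytest.approx(1.0)

    def test_dominance_is_computed_ratio_d5(self):
        # five-harmonic shape built so max_{l!=1} a_l / a_1 = 0.59
        a = np.array([1.0, 0.59, 0.40, 0.20, 0.10])
        theta = np.array([0.0, 0.7, 1.4, 2.1, 2.8])
        s = ps.wave_shape_from_harmonics(a, theta, a0=0.1)
        assert s.D == 5
        assert s.theta == 0.0
        assert s.delta == pytest.approx(0.59)

    def test_degenerate_fundamental_raises(self):
        with pytest.raises(DegenerateShapeError):
            ps.make_wave_shape([0.5, 0.0, 1.0], [0.0, 0.0])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_periodicity(self, seed):
        rng = np.random.default_rng(seed)
        s = ps.make_wave_shape(rng.normal(size=7) + [0, 2, 0, 0, 0, 0, 0],
                               rng.normal(size=6))
        u = rng.uniform(-3, 3, size=50)
        np.testing.assert_allclose(s(u), s(u + 1.0), atol=1e-12)

    def test_harmonic_parameterization_identity(self):
        # alpha_l = 2 a_l cos(theta_l), beta_l = -2 a_l sin(theta_l)
        # implies s(u) = a0 + 2 sum a_l cos(2 pi l u + theta_l)
        a = np.array([0.5, 0.2, 0.1])
        theta = np.array([0.3, 1.1, 2.9])
        s = ps.wave_shape_from_harmonics(a, theta, a0=0.4)
        u = np.linspace(0, 1, 37)
        direct = 0.4 + sum(2 * a[l] * np.cos(2 * np.pi * (l + 1) * u
                                             + theta[l]) for l in range(3))
        np.testing.assert_allclose(s(u), direct, atol=1e-12)
        np.testing.assert_allclose(s.harmonic_amplitudes[1:], a)


class TestIMTParameters:
    def test_linear_phase_tone(self):
        p = ps.hrv_phase(100.0, 10.0, mean_if=1.2,
                         if_modulation=ps.ModulationSpec("none"))
        np.testing.assert_allclose(p.phiprime, 1.2)
        np.testing.assert_allclose(p.phi, 1.2 * np.arange(1000) / 100.0,
                                   atol=1e-9)

    def test_sinusoidal_modulation_bounds(self):
        p = ps.hrv_phase(100.0, 10.0, mean_if=1.0,
                         if_modulation=ps.ModulationSpec(
                             "sinusoid", depth=0.1, freq=0.1, phase=0.25))
        assert p.phiprime.min() >= 0.9 - 1e-12
        assert p.phiprime.max() <= 1.1 + 1e-12
        assert np.all(np.diff(p.phi) > 0)

    def test_generated_traces_satisfy_declared_regularity(self):
        rng = np.random.default_rng(3)
        for kind in ("sinusoid", "filtered_noise"):
            p = ps.hrv_phase(100.0, 10.0, mean_if=1.1,
                             if_modulation=ps.ModulationSpec(kind, 0.1, 0.1),
                             am_modulation=ps.ModulationSpec(kind, 0.1, 0.15),
                             rng=rng)
            assert p.is_regular()

    def test_known_phase_regularity_bound(self):
        # phi(t) = t + 0.05 sin(2 pi 0.1 t)/(2 pi 0.1): |phi''| <= 0.05*2pi*0.1
        fs, dur = 100.0, 10.0
        t = np.arange(int(fs * dur)) / fs
        phiprime = 1.0 + 0.05 * np.cos(2 * np.pi * 0.1 * t)
        phi = t + 0.05 * np.sin(2 * np.pi * 0.1 * t) / (2 * np.pi * 0.1)
        p = ps.IMTParameters(A=np.ones_like(t), phi=phi, phiprime=phiprime,
                             epsilon=0.06, fs=fs)
        assert p.is_regular(0.06)

    def test_excessive_modulation_raises(self):
        with pytest.raises(ValueError):
            ps.hrv_phase(100.0, 10.0, mean_if=1.0,
                         if_modulation=ps.ModulationSpec("sinusoid", 1.5, 0.1,
                                                         phase=0.0))

    def test_seeded_determinism(self):
        a = ps.hrv_phase(100.0, 5.0, rng=7,
                         if_modulation=ps.ModulationSpec("filtered_noise",
                                                         0.05, 0.1))
        b = ps.hrv_phase(100.0, 5.0, rng=7,
                         if_modulation=ps.ModulationSpec("filtered_noise",
                                                         0.05, 0.1))
        np.testing.assert_array_equal(a.phi, b.phi)


class TestSynthesis:
    def test_tone_matches_direct_cosine(self):
        shape = ps.make_wave_shape([0.0, 1.0], [0.0])
        p = ps.hrv_phase(100.0, 10.0, mean_if=1.2,
                         if_modulation=ps.ModulationSpec("none"))
        sig = ps.synthesize_imt(shape, p)
        t = np.arange(1000) / 100.0
        np.testing.assert_allclose(sig.samples, np.cos(2 * np.pi * 1.2 * t),
                                   atol=1e-9)

    def test_constant_amplitude_linear_phase_oracle(self):
        # direct trigonometric evaluation as the oracle
        rng = np.random.default_rng(0)
        shape = ps.make_wave_shape(rng.normal(size=5) + [0, 2, 0, 0, 0],
                                   rng.normal(size=4))
        fs, f0, A = 50.0, 0.9, 2.5
        t = np.arange(200) / fs
        p = ps.IMTParameters(A=np.full(t.size, A), phi=f0 * t,
                             phiprime=np.full(t.size, f0), epsilon=1e-9,
                             fs=fs)
        sig = ps.synthesize_imt(shape, p)
        direct = A * (shape.alpha[0]
                      + sum(shape.alpha[l] * np.cos(2 * np.pi * l * f0 * t)
                            + shape.beta[l - 1] * np.sin(2 * np.pi * l * f0 * t)
                            for l in range(1, 5)))
        np.testing.assert_allclose(sig.samples, direct, atol=1e-12)

    def test_zero_amplitude_gives_zero_signal(self):
        shape = ps.make_wave_shape([0.0, 1.0], [0.0])
        t = np.arange(100) / 10.0
        p = ps.IMTParameters(A=np.zeros(100), phi=t, phiprime=np.ones(100),
                             epsilon=1e-9, fs=10.0)
        assert not ps.synthesize_imt(shape, p).samples.any()


class TestNoise:
    def test_recursion_matches_manual_loop(self):
        # a(z)=1+0.5z, b(z)=1-0.3z  ->  x[k] = -0.5 x[k-1] + e[k] - 0.3 e[k-1]
        rng = np.random.default_rng(1)
        e = rng.standard_t(3, size=600)

        class _FixedRng:
            def standard_t(self, dof, size):
                return e[:size]

        x = ps.arma_t_noise(100, ps.NoiseModel(), rng=_FixedRng(),
                            burn_in=500)
        manual = np.zeros(600)
        for k in range(600):
            manual[k] = (-0.5 * (manual[k - 1] if k else 0.0) + e[k]
                         - 0.3 * (e[k - 1] if k else 0.0))
        manual = manual[500:]
        np.testing.assert_allclose(x, manual / manual.std(), atol=1e-12)

    def test_unit_standard_deviation(self):
        x = ps.arma_t_noise(10_000, rng=np.random.default_rng(2))
        assert x.std() == pytest.approx(1.0, abs=1e-12)  # exact by scaling

    def test_lag1_autocorrelation_matches_closed_form(self):
        from pulsesst.model import arma1_acf1
        n = 100_000
        x = ps.arma_t_noise(n, rng=np.random.default_rng(3))
        r1 = float(np.corrcoef(x[:-1], x[1:])[0, 1])
        expected = arma1_acf1(phi=-0.5, theta=-0.3)
        assert expected == pytest.approx(-0.662, abs=5e-3)
        assert r1 == pytest.approx(expected, abs=3.0 / np.sqrt(n) * 3)

    def test_gaussian_white_option(self):
        x = ps.arma_t_noise(50_000, ps.NoiseModel(ar=(1.0,), ma=(1.0,),
                                                  dof=np.inf),
                            rng=np.random.default_rng(4))
        r1 = float(np.corrcoef(x[:-1], x[1:])[0, 1])
        assert abs(r1) < 0.02

    def test_t3_innovations_are_heavy_tailed(self):
        from scipy.stats import kurtosis
        rng = np.random.default_rng(5)
        e = rng.standard_t(3, size=100_000)
        assert kurtosis(e) > 3.0  # excess kurtosis far above Gaussian 0

    def test_nonstationary_ar_rejected(self):
        with pytest.raises(ValueError):
            ps.NoiseModel(ar=(1.0, -1.5))


class TestSNR:
    @pytest.mark.parametrize("snr_db,ratio", [(0.0, 1.0), (20.0, 10.0)])
    def test_exact_scaling(self, snr_db, ratio):
        rng = np.random.default_rng(6)
        clean = ps.PulseSignal(np.sin(np.arange(500) * 0.1), 100.0)
        noise = rng.normal(size=500)
        noisy = ps.add_noise_at_snr(clean, noise, snr_db)
        scaled = noisy.samples - clean.samples
        assert clean.samples.std() / scaled.std() == pytest.approx(
            ratio, rel=1e-12)

    def test_high_snr_limit(self):
        clean = ps.PulseSignal(np.sin(np.arange(500) * 0.1), 100.0)
        noisy = ps.add_noise_at_snr(clean, np.ones(500) + 0.1 *
                                    np.sin(np.arange(500)), 200.0)
        np.testing.assert_allclose(noisy.samples, clean.samples, atol=1e-8)

    def test_zero_variance_signal_rejected(self):
        flat = ps.PulseSignal(np.ones(100), 10.0)
        with pytest.raises(ValueError):
            ps.add_noise_at_snr(flat, np.random.default_rng(0).normal(
                size=100), 0.0)


class TestCohortGenerator:
    def test_record_geometry(self):
        ds = ps.simulate_cohort(2, 2, seed=0)
        assert ds.n == 4
        assert all(r.n == 1000 and r.fs == 100.0 for r in ds.records)
        np.testing.assert_array_equal(ds.labels, [0, 0, 1, 1])

    def test_seeded_reproducibility(self):
        a = ps.simulate_cohort(2, 2, seed=9)
        b = ps.simulate_cohort(2, 2, seed=9)
        for ra, rb in zip(a.records, b.records):
            np.testing.assert_array_equal(ra.samples, rb.samples)

    def test_within_group_spread_and_canonical_gauge(self):
        rng = np.random.default_rng(11)
        shapes = [_jitter_shape(ps.control_template(), 0.02, rng)
                  for _ in range(50)]
        for s in shapes:
            assert s.energy == pytest.approx(1.0)
            assert s.beta[0] == 0.0
        a1 = np.array([s.alpha[1] for s in shapes])
        assert 0.005 < a1.std() < 0.06

    def test_generated_parameters_satisfy_regularity(self):
        ds = ps.simulate_cohort(3, 3, seed=1)
        for meta in ds.metadata:
            assert meta["params"].is_regular()
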