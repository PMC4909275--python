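"""Functional design matrix, SPS least squares, and shape reconstruction."""
import numpy as np
import pytest

import pulsesst as ps
from pulsesst.regression import ConditioningError
from pulsesst.ridge import Demodulation


def oracle_demod(params, t):
    """Demodulation carrying the generator's exact A and phi."""
    return Demodulation(R=params.A.astype(complex), A=params.A,
                        phase=params.phi, times=t)


@pytest.fixture(scope="module")
def noiseless_case():
    rng = np.random.default_rng(21)
    from pulsesst.model import _jitter_shape
    shape = _jitter_shape(ps.control_template(), 0.02, rng)
    params = ps.hrv_phase(
        100.0, 10.0, mean_if=1.1,
        if_modulation=ps.ModulationSpec("sinusoid", 0.1, 0.1, phase=0.3),
        am_modulation=ps.ModulationSpec("sinusoid", 0.1, 0.15, phase=0.1))
    sig = ps.synthesize_imt(shape, params)
    return shape, params, sig


class TestDesign:
    def test_row_zero_is_amplitude(self, noiseless_case):
        _, params, sig = noiseless_case
        d = ps.build_design(oracle_demod(params, sig.t), D=6)
        np.testing.assert_array_equal(d.c[0], params.A)

    def test_d6_gives_13_rows(self, noiseless_case):
        _, params, sig = noiseless_case
        assert ps.build_design(oracle_demod(params, sig.t), D=6).c.shape[0] \
            == 13

    def test_harmonic_orthogonality_over_whole_periods(self):
        # unit amplitude, linear phase over exactly P periods:
        # dt * c c^T ~ diag(T, T/2, ..., T/2)
        fs, P = 100.0, 10
        t = np.arange(int(fs * P)) / fs  # phi = t covers P whole cycles
        demod = Demodulation(R=np.ones(t.size, complex), A=np.ones(t.size),
                             phase=t, times=t)
        d = ps.build_design(demod, D=3)
        G = d.c @ d.c.T / fs
        T = P * 1.0
        expected = np.diag([T] + [T / 2] * 6)
        np.testing.assert_allclose(G, expected, atol=0.02)

    def test_diagonal_dominance_on_fixture(self, noiseless_case):
        _, params, sig = noiseless_case
        d = ps.build_design(oracle_demod(params, sig.t), D=6)
        G = np.abs(d.c @ d.c.T * (1.0 / 100.0))
        diag = np.diag(G)
        off = G - np.diag(diag)
        assert np.all(diag > off.sum(axis=1))

    def test_too_short_record_rejected(self):
        t = np.arange(20) / 100.0
        demod = Demodulation(R=np.ones(20, complex), A=np.ones(20),
                             phase=1.1 * t, times=t)
        with pytest.raises(ValueError):
            ps.build_design(demod, D=6)


class TestFit:
    def test_oracle_demodulation_is_exact(self, noiseless_case):
        shape, params, sig = noiseless_case
        d = ps.build_design(oracle_demod(params, sig.t), D=6)
        gamma = ps.fit_sps(sig, d).gamma
        truth = np.concatenate((shape.alpha, shape.beta))
        assert np.abs(gamma - truth).max() / np.abs(truth).max() < 1e-8

    def test_zero_signal_gives_zero_sps(self, noiseless_case):
        _, params, sig = noiseless_case
        d = ps.build_design(oracle_demod(params, sig.t), D=6)
        assert not ps.fit_sps(np.zeros(sig.n), d).gamma.any()

    def test_white_noise_errors_within_ols_theory(self, noiseless_case):
        # |gamma_hat - gamma| <= 4 SE with SE from the OLS covariance;
        # over 100 seeds x 13 coefficients, flags should be very rare
        shape, params, sig = noiseless_case
        d = ps.build_design(oracle_demod(params, sig.t), D=6)
        truth = np.concatenate((shape.alpha, shape.beta))
        Ginv = np.linalg.inv(d.c @ d.c.T)
        se = np.sqrt(np.diag(Ginv))  # unit-variance noise
        rng = np.random.default_rng(31)
        flags = 0
        for _ in range(100):
            y = sig.samples + rng.standard_normal(sig.n)
            gamma = ps.fit_sps(y, d).gamma
            flags += int(np.any(np.abs(gamma - truth) > 4.0 * se))
        assert flags <= 2

    def test_constant_phase_raises(self):
        t = np.arange(500) / 100.0
        demod = Demodulation(R=np.ones(500, complex), A=np.ones(500),
                             phase=1e-9 * t, times=t)
        d = ps.build_design(demod, D=6)
        with pytest.raises((ConditioningError, Warning)):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                ps.fit_sps(np.ones(500), d)


class TestReconstructAndPower:
    def test_noiseless_reconstruction_exact(self, noiseless_case):
        shape, params, sig = noiseless_case
        d = ps.build_design(oracle_demod(params, sig.t), D=6)
        sps = ps.fit_sps(sig, d)
        f = ps.reconstruct_signal(sps, d)
        assert (np.linalg.norm(f - sig.samples)
                / np.linalg.norm(sig.samples)) < 1e-8

    def test_zero_sps_reconstructs_zero(self, noiseless_case):
        _, params, sig = noiseless_case
        d = ps.build_design(oracle_demod(params, sig.t), D=6)
        z = ps.SPSVector(gamma=np.zeros(13), D=6)
        assert not ps.reconstruct_signal(z, d).any()

    def test_estimated_path_reconstruction(self, noiseless_case):
        shape, params, sig = noiseless_case
        res = ps.analyze_record(sig)
        inner = res.interior
        d = ps.build_design(
            Demodulation(R=res.demod.R[inner], A=res.demod.A[inner],
                         phase=res.demod.phase[inner],
                         times=res.demod.times[inner]), D=6)
        f = ps.reconstruct_signal(res.sps, d)
        rel = (np.linalg.norm(f - sig.samples[inner])
               / np.linalg.norm(sig.samples[inner]))
        assert rel <= 0.1

    def test_harmonic_power_identity(self):
        a = np.array([0.5, 0.3, 0.1])
        theta = np.array([0.4, 1.2, 2.8])
        s = ps.wave_shape_from_harmonics(a, theta, a0=0.2)
        sps = ps.SPSVector(np.concatenate((s.alpha, s.beta)), D=3)
        np.testing.assert_allclose(ps.harmonic_power(sps), a ** 2,
                                   atol=1e-14)

    def test_pure_cosine_power(self):
        sps = ps.SPSVector(np.array([0, 1, 0, 0, 0, 0, 0], float), D=3)
        np.testing.assert_allclose(ps.harmonic_power(sps),
                                   [0.25, 0, 0], atol=1e-15)

    def test_power_invariant_under_phase_rotation(self):
        rng = np.random.default_rng(41)
        g = rng.normal(size=13)
        sps = ps.SPSVector(g, D=6)
        psi = 0.83
        rot = g.copy()
        for l in range(1, 7):
            al, bl = g[l], g[6 + l]
            rot[l] = al * np.cos(psi) + bl * np.sin(psi)
            rot[6 + l] = -al * np.sin(psi) + bl * np.cos(psi)
        np.testing.assert_allclose(ps.harmonic_power(sps),
                                   ps.harmonic_power(ps.SPSVector(rot, D=6)),
                                   atol=1e-12)

    def test_shape_round_trip(self, noiseless_case):
        shape, params, sig = noiseless_case
        d = ps.build_design(oracle_demod(params, sig.t), D=6)
        sps = ps.fit_sps(sig, d)
        u = np.arange(256) / 256
        np.testing.assert_allclose(ps.sps_to_shape(sps, 256),
                                   ps.eval_wave_shape(shape, u), atol=1e-8)

    def test_shape_mean_equals_alpha0(self):
        rng = np.random.default_rng(5)
        sps = ps.SPSVector(rng.normal(size=13), D=6)
        assert ps.sps_to_shape(sps, 512).mean() == pytest.approx(
            sps.gamma[0], abs=1e-12)

    def test_normalize_sps_unit_energy(self):
        rng = np.random.default_rng(6)
        sps = ps.normalize_sps(ps.SPSVector(rng.normal(size=13), D=6))
        assert sps.energy == pytest.approx(1.0, rel=1e-12)


class TestHRVInvariance:
    def test_sps_invariant_to_phase_function(self):
        from pulsesst.protocols import hrv_invariance_protocol
        out = hrv_invariance_protocol(seed=11)
        assert out["rel_diff"] <= 0.02

    def test_phase_vs_power_distinction(self):
        # identical harmonic magnitudes, different phases: same power
        # spectrum, different SPS
        a = np.array([0.5, 0.25, 0.12])
        s1 = ps.wave_shape_from_harmonics(a, np.array([0.0, 0.8, 1.6]))
        s2 = ps.wave_shape_from_harmonics(a, np.array([0.0, 1.4, 2.9]))
        g1 = ps.SPSVector(np.concatenate((s1.alpha, s1.beta)), D=3)
        g2 = ps.SPSVector(np.concatenate((s2.alpha, s2.beta)), D=3)
        np.testing.assert_allclose(ps.harmonic_power(g1),
                                   ps.harmonic_power(g2), atol=1e-14)
        assert np.abs(g1.gamma - g2.gamma).max() > 0.05
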