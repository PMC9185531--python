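"""Physics of the synthetic echo model: Fresnel, Snell, lossy propagation."""

import math

import numpy as np
import pytest
from scipy.constants import epsilon_0, mu_0

from glucowave.config import DEFAULT_CONCENTRATIONS, DielectricLaw, SimulationConfig
from glucowave.simulate import (
    MediumProperties,
    SceneGeometry,
    attenuated_field,
    concentration_to_medium,
    echo_amplitude,
    propagation_constants,
    reflection_coeff_s,
    snell_angle,
    synthesize_beat_signal,
)


class TestMediumProperties:
    def test_loss_tangent_consistency_enforced(self):
        with pytest.raises(ValueError):
            MediumProperties(eps_real=4.0, eps_imag=1.0, sigma=0.1, loss_tangent=0.5)

    def test_from_loss_tangent_roundtrip(self):
        m = MediumProperties.from_loss_tangent(6.5, 0.03, omega=2 * math.pi * 77e9)
        assert m.loss_tangent == pytest.approx(abs(m.eps_imag) / m.eps_real, abs=1e-12)
        assert m.sigma > 0

    def test_nonpositive_permittivity_rejected(self):
        with pytest.raises(ValueError):
            MediumProperties(eps_real=0.0, eps_imag=0.0, sigma=0.0)


class TestDielectricLaw:
    def test_monotone_trends(self):
        law = DielectricLaw()
        c1, c2 = 0.7, 1.1
        m1 = concentration_to_medium(c1, law)
        m2 = concentration_to_medium(c2, law)
        assert m1.eps_real < m2.eps_real
        assert m1.loss_tangent > m2.loss_tangent

    def test_deterministic(self):
        a = concentration_to_medium(0.91)
        b = concentration_to_medium(0.91)
        assert a == b

    def test_five_point_grid_sorted(self):
        # brute-force sort check over the default concentration grid
        law = DielectricLaw()
        eps = [concentration_to_medium(c, law).eps_real for c in DEFAULT_CONCENTRATIONS]
        tan = [
            concentration_to_medium(c, law).loss_tangent
            for c in DEFAULT_CONCENTRATIONS
        ]
        assert eps == sorted(eps)
        assert tan == sorted(tan, reverse=True)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            concentration_to_medium(3.0)


class TestSnell:
    def test_identical_media(self):
        assert snell_angle(0.5, 4.0, 4.0) == pytest.approx(0.5, abs=1e-12)

    def test_normal_incidence(self):
        assert snell_angle(0.0, 1.0, 9.0) == 0.0

    def test_closed_form_inversion(self):
        # sin(30 deg) / sqrt(4) = 0.25
        theta_t = snell_angle(math.radians(30), 1.0, 4.0)
        assert theta_t == pytest.approx(math.asin(0.25), abs=1e-12)

    def test_total_internal_reflection(self):
        with pytest.raises(ValueError, match="total internal"):
            snell_angle(math.radians(80), 9.0, 1.0)


class TestFresnelS:
    def test_no_contrast_is_zero(self):
        m = MediumProperties(1.0, 0.0, 0.0)
        assert reflection_coeff_s(0.3, 0.3, m, m) == pytest.approx(0.0, abs=1e-12)

    def test_normal_incidence_closed_form(self):
        # |1 - sqrt(9)| / |1 + sqrt(9)| = 0.5
        m2 = MediumProperties(9.0, 0.0, 0.0)
        assert reflection_coeff_s(0.0, 0.0, m2=m2) == pytest.approx(0.5, abs=1e-12)

    def test_increasing_in_permittivity(self):
        theta_i = math.radians(20)
        coeffs = []
        for eps2 in (3.0, 5.0, 8.0):
            theta_t = snell_angle(theta_i, 1.0, eps2)
            coeffs.append(
                reflection_coeff_s(
                    theta_i, theta_t, m2=MediumProperties(eps2, 0.0, 0.0)
                )
            )
        assert coeffs == sorted(coeffs)

    def test_matches_sine_form_at_oblique_incidence(self):
        theta_i = math.radians(35)
        eps2 = 6.0
        theta_t = snell_angle(theta_i, 1.0, eps2)
        sine_form = abs(math.sin(theta_i - theta_t) / math.sin(theta_i + theta_t))
        n_form = reflection_coeff_s(theta_i, theta_t, m2=MediumProperties(eps2, 0, 0))
        assert n_form == pytest.approx(sine_form, rel=1e-12)


class TestPropagation:
    OMEGA = 2 * math.pi * 77e9

    def test_lossless_limit(self):
        m = MediumProperties(6.5, 0.0, 0.0)
        alpha, beta = propagation_constants(m, self.OMEGA)
        assert alpha == 0.0
        assert beta == pytest.approx(
            self.OMEGA * math.sqrt(mu_0 * epsilon_0 * 6.5), rel=1e-12
        )

    def test_alpha_increases_with_conductivity(self):
        m1 = MediumProperties.from_loss_tangent(6.5, 0.02, self.OMEGA)
        m2 = MediumProperties.from_loss_tangent(6.5, 0.04, self.OMEGA)
        a1, _ = propagation_constants(m1, self.OMEGA)
        a2, _ = propagation_constants(m2, self.OMEGA)
        assert 0 < a1 < a2

    @pytest.mark.parametrize("tan_delta", [0.0, 0.01, 0.3, 2.0])
    def test_algebraic_identity(self, tan_delta):
        # beta^2 - alpha^2 == omega^2 * mu * eps for any loss level
        m = MediumProperties.from_loss_tangent(6.5, tan_delta, self.OMEGA)
        alpha, beta = propagation_constants(m, self.OMEGA)
        lhs = beta**2 - alpha**2
        rhs = self.OMEGA**2 * mu_0 * epsilon_0 * 6.5
        assert lhs == pytest.approx(rhs, rel=1e-9)


class TestAttenuatedField:
    def test_zero_path(self):
        assert abs(attenuated_field(2.0, 5.0, 100.0, 0.0)) == pytest.approx(2.0)

    def test_half_amplitude_at_ln2_over_alpha(self):
        r = 0.01
        alpha = math.log(2) / r
        assert abs(attenuated_field(1.0, alpha, 50.0, r)) == pytest.approx(
            0.5, rel=1e-12
        )

    def test_exponential_semigroup(self):
        e1 = abs(attenuated_field(1.0, 30.0, 40.0, 0.02))
        e2 = abs(attenuated_field(1.0, 30.0, 40.0, 0.04))
        assert e2 == pytest.approx(e1**2, rel=1e-9)

    def test_phase_advance(self):
        f = attenuated_field(1.0, 0.0, 2.0, 1.0, omega=0.0, t=0.0)
        assert np.angle(f) == pytest.approx(-2.0, abs=1e-12)


class TestEchoAmplitude:
    def test_no_backplate(self):
        geom = SceneGeometry(backplate_reflectivity=0.0)
        law = DielectricLaw()
        medium = concentration_to_medium(0.91, law)
        theta_t = snell_angle(0.0, 1.0, medium.eps_real)
        front = reflection_coeff_s(0.0, theta_t, m2=medium)
        assert echo_amplitude(0.91, geom, law) == pytest.approx(front, rel=1e-12)

    def test_opaque_solution_limit(self):
        # a very lossy law drives the back-plate term to zero
        law = DielectricLaw(b0=5.0, b1=0.0)
        geom = SceneGeometry()
        medium = concentration_to_medium(0.91, law)
        theta_t = snell_angle(0.0, 1.0, medium.eps_real)
        front = reflection_coeff_s(0.0, theta_t, m2=medium)
        assert abs(echo_amplitude(0.91, geom, law)) == pytest.approx(
            front, rel=1e-6
        )

    def test_monotone_over_default_classes(self):
        mags = [abs(echo_amplitude(c)) for c in DEFAULT_CONCENTRATIONS]
        assert all(a < b for a, b in zip(mags, mags[1:]))


class TestBeatSignal:
    def test_noiseless_tone_is_deterministic(self):
        cfg = SimulationConfig()
        sig = synthesize_beat_signal(0.91, cfg, noise=False, drift=False)
        n = cfg.n_samples
        amp = echo_amplitude(0.91) * cfg.antenna_gains[0]
        expected = amp * np.exp(
            2j * math.pi * cfg.beat_freq_bins * np.arange(n) / n
        )
        np.testing.assert_allclose(sig.samples, expected, rtol=1e-12)

    def test_seeded_records_bitwise_identical(self):
        a = synthesize_beat_signal(0.81, seed=42, power_cycle_id=3)
        b = synthesize_beat_signal(0.81, seed=42, power_cycle_id=3)
        assert np.array_equal(a.samples, b.samples)

    def test_default_record_length(self):
        assert synthesize_beat_signal(0.69).n_samples == 64

    def test_noise_variance_matches_snr(self):
        # Monte-Carlo estimate of the injected noise power vs configured
        cfg = SimulationConfig(snr_db=20.0)
        clean = synthesize_beat_signal(0.91, cfg, noise=False, drift=False)
        noises = []
        for i in range(100):
            noisy = synthesize_beat_signal(
                0.91, cfg, seed=i, noise=True, drift=False
            )
            noises.append(noisy.samples - clean.samples)
        measured = np.mean([np.mean(np.abs(d) ** 2) for d in noises])
        amp = abs(echo_amplitude(0.91)) * cfg.antenna_gains[0]
        expected = amp**2 / 10.0**2
        assert measured == pytest.approx(expected, rel=0.2)

    def test_noise_is_high_frequency(self):
        cfg = SimulationConfig()
        clean = synthesize_beat_signal(0.91, cfg, noise=False, drift=False)
        noisy = synthesize_beat_signal(0.91, cfg, seed=5, noise=True, drift=False)
        spec = np.fft.fft(noisy.samples - clean.samples)
        n = cfg.n_samples
        low = np.sum(np.abs(spec[: n // 4]) ** 2) + np.sum(
            np.abs(spec[3 * n // 4 + 1 :]) ** 2
        )
        high = np.sum(np.abs(spec[n // 4 : 3 * n // 4 + 1]) ** 2)
        assert high > 100 * low

    def test_invalid_snr_rejected(self):
        with pytest.raises(ValueError):
            synthesize_beat_signal(0.91, SimulationConfig(snr_db=-math.inf))

    def test_drift_changes_gain_between_cycles(self):
        cfg = SimulationConfig()
        a = synthesize_beat_signal(0.91, cfg, power_cycle_id=0, noise=False)
        b = synthesize_beat_signal(0.91, cfg, power_cycle_id=1, noise=False)
        assert not np.allclose(a.samples, b.samples)
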