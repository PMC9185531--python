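"""EMD sifting, the 3*f0 rejection rule, and db10 wavelet denoising."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucowave.denoise import (
    EmdDecomposition,
    FrequencyLabel,
    classify_and_filter,
    denoise_complex,
    dwt_denoise,
    emd_decompose,
    emd_denoise,
    zero_crossing_count,
)
from glucowave.simulate import synthesize_beat_signal
from glucowave.spectral import psd, total_energy, zero_pad


class TestZeroCrossings:
    def test_constant_positive(self):
        assert zero_crossing_count(np.ones(50)) == 0

    def test_sine_crossings_match_analytic_count(self):
        # densely sampled sine with a small phase lead: the analytic zero
        # count over the window is 2m for m full periods
        for m in (1, 3, 7):
            t = np.arange(2000) / 2000
            x = np.sin(2 * np.pi * m * t - 0.3)
            # zeros at t = (0.3 + k*pi) / (2*pi*m) for k = 0 .. 2m-1
            assert zero_crossing_count(x) == 2 * m

    def test_negation_invariance(self, rng):
        x = rng.standard_normal(200)
        assert zero_crossing_count(x) == zero_crossing_count(-x)

    def test_all_zero(self):
        assert zero_crossing_count(np.zeros(10)) == 0

    def test_exact_zero_counted_once(self):
        assert zero_crossing_count(np.array([1.0, 0.0, -1.0])) == 1
        assert zero_crossing_count(np.array([1.0, 0.0, 1.0])) == 0


class TestEmd:
    def test_monotone_ramp_yields_no_imfs(self):
        x = np.linspace(0.0, 1.0, 64)
        dec = emd_decompose(x)
        assert dec.imfs == []
        np.testing.assert_array_equal(dec.residual, x)

    def test_first_imf_captures_fast_tone(self):
        n = 256
        t = np.arange(n)
        fast = np.sin(2 * np.pi * 0.2 * t)
        slow = 2.0 * np.sin(2 * np.pi * 0.01 * t)
        dec = emd_decompose(fast + slow)
        assert len(dec.imfs) >= 1
        corr = np.corrcoef(dec.imfs[0], fast)[0, 1]
        assert corr > 0.9

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_reconstruction_identity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(64)
        dec = emd_decompose(x)
        rel = np.max(np.abs(dec.reconstruct() - x)) / max(np.max(np.abs(x)), 1e-12)
        assert rel < 1e-8

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            emd_decompose(np.ones(4))


def _tone_with_crossings(n_crossings: int, length: int = 512) -> np.ndarray:
    """Dense sine whose zero count over the window is exactly
    ``n_crossings``: zeros sit at ``t = (0.3 + k pi) / (2 pi nu)`` and the
    frequency ``nu`` is chosen so exactly that many fall inside (0, 1)."""
    nu = n_crossings / 2 - 0.05
    t = np.arange(length) / length
    return np.sin(2 * np.pi * nu * t - 0.3)


class TestRejectionRule:
    def test_boundary_component_removed_and_below_kept(self):
        f0 = 4
        keep = _tone_with_crossings(3 * f0 - 1)
        drop = _tone_with_crossings(3 * f0)
        assert zero_crossing_count(keep) == 3 * f0 - 1
        assert zero_crossing_count(drop) == 3 * f0
        residual = np.linspace(0, 0.5, len(keep))
        dec = EmdDecomposition(imfs=[drop, keep], residual=residual)
        out = classify_and_filter(dec, f0)
        np.testing.assert_allclose(out, residual + keep, atol=1e-12)

    def test_nothing_removed_when_all_slow(self):
        f0 = 10
        imfs = [_tone_with_crossings(4), _tone_with_crossings(8)]
        residual = np.zeros(512)
        dec = EmdDecomposition(imfs=imfs, residual=residual)
        out = classify_and_filter(dec, f0)
        np.testing.assert_allclose(out, imfs[0] + imfs[1], atol=1e-12)

    def test_label_property(self):
        assert FrequencyLabel(f0=4, fi=12).label == "high"
        assert FrequencyLabel(f0=4, fi=11).label == "low"

    def test_denoising_recovers_slow_tone(self, rng):
        n = 256
        t = np.arange(n)
        clean = np.sin(2 * np.pi * 0.02 * t)
        noise = 0.3 * np.sin(2 * np.pi * 0.35 * t)
        noisy = clean + noise
        out = emd_denoise(noisy)
        rmse_out = np.sqrt(np.mean((out - clean) ** 2))
        rmse_in = np.sqrt(np.mean((noisy - clean) ** 2))
        assert rmse_out < rmse_in


class TestDwt:
    def test_zero_threshold_reconstructs_exactly(self, rng):
        x = rng.standard_normal(64)
        out = dwt_denoise(x, threshold=0.0)
        np.testing.assert_allclose(out, x, atol=1e-8)

    def test_zero_input(self):
        assert np.all(dwt_denoise(np.zeros(64)) == 0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            dwt_denoise(np.ones(8))

    def test_noise_reduction_on_slow_tone(self, rng):
        # 20-trial Monte-Carlo: denoised RMSE strictly below noisy RMSE
        n = 64
        t = np.arange(n)
        clean = np.sin(2 * np.pi * 3.3 * t / n)
        gains = []
        for _ in range(20):
            noisy = clean + 0.3 * rng.standard_normal(n)
            out = dwt_denoise(noisy)
            gains.append(
                np.sqrt(np.mean((noisy - clean) ** 2))
                - np.sqrt(np.mean((out - clean) ** 2))
            )
        assert np.mean(gains) > 0


class TestComplexPlumbing:
    def test_real_input_stays_real(self):
        x = np.sin(2 * np.pi * 3 * np.arange(64) / 64).astype(complex)
        out = denoise_complex(x, "dwt")
        assert np.max(np.abs(out.imag)) == 0

    def test_conjugation_symmetry(self):
        sig = synthesize_beat_signal(0.91, seed=3)
        a = denoise_complex(np.conj(sig.samples), "dwt")
        b = np.conj(denoise_complex(sig.samples, "dwt"))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_matches_partwise_application(self):
        sig = synthesize_beat_signal(0.81, seed=9)
        x = sig.samples
        expected = dwt_denoise(x.real) + 1j * dwt_denoise(x.imag)
        np.testing.assert_allclose(denoise_complex(x, "dwt"), expected, atol=1e-12)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            denoise_complex(np.ones(64, dtype=complex), "median")


class TestLowBandFidelity:
    """Energy-preserving behaviour of the denoisers on simulator output."""

    @staticmethod
    def _lowband_error(denoised, clean):
        n = len(clean)
        lo = (16 * n) // 8
        p_d = psd(zero_pad(denoised), n)
        p_c = psd(zero_pad(clean), n)
        band = slice(0, lo // 2)  # positive-frequency half of the low band
        return np.linalg.norm(p_d[band] - p_c[band]) / np.linalg.norm(p_c[band])

    def test_dwt_beats_emd_in_the_low_band(self):
        dwt_errs, emd_errs = [], []
        for i in range(10):
            clean = synthesize_beat_signal(0.91, seed=i, noise=False, drift=False)
            noisy = synthesize_beat_signal(0.91, seed=i, noise=True, drift=False)
            d_dwt = denoise_complex(noisy.samples, "dwt")
            d_emd = denoise_complex(noisy.samples, "emd")
            dwt_errs.append(self._lowband_error(d_dwt, clean.samples))
            emd_errs.append(self._lowband_error(d_emd, clean.samples))
        assert np.mean(dwt_errs) < 0.1
        assert np.mean(emd_errs) >= np.mean(dwt_errs)

    def test_denoising_removes_energy_on_average(self):
        # components are only removed or shrunk; neither decomposition is
        # exactly orthogonal on short records, so single records may gain a
        # fraction of a percent, but energy must fall on average and never
        # grow materially
        for method in ("emd", "dwt"):
            e_in_all, e_out_all = [], []
            for i in range(8):
                noisy = synthesize_beat_signal(0.91, seed=i)
                out = denoise_complex(noisy.samples, method)
                e_in = total_energy(psd(zero_pad(noisy.samples), 64))
                e_out = total_energy(psd(zero_pad(out), 64))
                assert e_out <= e_in * 1.01
                e_in_all.append(e_in)
                e_out_all.append(e_out)
            assert np.mean(e_out_all) < np.mean(e_in_all)
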