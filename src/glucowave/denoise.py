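"""High-frequency noise removal: EMD zero-crossing filtering and db10 DWT.

Thermal noise in the beat records concentrates above the beat tone, so the
pipeline removes it with one of two low-pass strategies:

* **EMD** — the record is sifted into intrinsic mode functions (IMFs)
  ordered fast-to-slow.  An IMF whose zero-crossing count ``f_i`` reaches
  three times the zero-crossing count ``f_0`` of the raw record is labelled
  high-frequency and dropped; the signal is rebuilt from the residual plus
  the surviving IMFs.
* **DWT** — a 3-level Daubechies-10 decomposition with symmetric extension;
  detail coefficients are soft-thresholded at the universal threshold
  ``sigma_hat * sqrt(2 ln n)`` with ``sigma_hat`` estimated from the median
  absolute deviation of the level-1 details, and the record is rebuilt.

Beat records are complex; each method is applied to the real and imaginary
parts independently and the parts are recombined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.interpolate import CubicSpline

#: rejection rule: IMF i is "high frequency" iff f_i >= HF_RATIO * f_0
HF_RATIO = 3

#: sifting stop criterion (standard-deviation criterion) and iteration cap
SIFT_SD_TOL = 0.2
MAX_SIFT_ITER = 10
DEFAULT_MAX_IMFS = 8


@dataclass
class EmdDecomposition:
    """IMFs plus residual of one real record; their sum is the input."""

    imfs: list[np.ndarray]
    residual: np.ndarray

    @property
    def source_length(self) -> int:
        return len(self.residual)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


@dataclass
class FrequencyLabel:
    """Zero-crossing bookkeeping for one IMF against the raw record."""

    f0: int
    fi: int

    @property
    def label(self) -> str:
        return "high" if self.fi >= HF_RATIO * self.f0 else "low"


def zero_crossing_count(x: np.ndarray) -> int:
    """Count sign changes between consecutive samples.

    Exact zeros are transparent: a run of zero samples contributes a single
    crossing when its neighbours have opposite signs, and none otherwise.
    An all-zero sequence has zero crossings.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    signs = np.sign(x)
    nz = signs[signs != 0]
    if nz.size < 2:
        return 0
    return int(np.count_nonzero(nz[1:] != nz[:-1]))


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateau midpoints)."""
    n = len(x)
    dx = np.diff(x)
    maxima, minima = [], []
    i = 0
    while i < n - 1:
        if dx[i] == 0:
            j = i
            while j < n - 1 and dx[j] == 0:
                j += 1
            if i > 0 and j < n - 1:
                if dx[i - 1] > 0 and dx[j] < 0:
                    maxima.append((i + j) // 2)
                elif dx[i - 1] < 0 and dx[j] > 0:
                    minima.append((i + j) // 2)
            i = j
        else:
            if 0 < i and dx[i - 1] > 0 and dx[i] < 0:
                maxima.append(i)
            elif 0 < i and dx[i - 1] < 0 and dx[i] > 0:
                minima.append(i)
            i += 1
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through the interior extrema.

    The record endpoints are included as envelope knots and one extremum is
    mirrored beyond each end, which pins the envelope at the boundaries and
    tames the spline overshoot that otherwise inflates boundary IMFs.
    """
    n = len(x)
    t = idx.astype(float)
    v = x[idx]
    t_ext = np.concatenate([[-t[0]], [0.0], t, [n - 1.0], [2 * (n - 1) - t[-1]]])
    v_ext = np.concatenate([[v[0]], [x[0]], v, [x[-1]], [v[-1]]])
    spline = CubicSpline(t_ext, v_ext)
    return spline(np.arange(n))


def _sift(x: np.ndarray) -> np.ndarray | None:
    """Extract one IMF from ``x``; None if ``x`` has too few extrema."""
    h = x.copy()
    for _ in range(MAX_SIFT_ITER):
        maxima, minima = _local_extrema(h)
        if len(maxima) < 2 or len(minima) < 2:
            return None
        upper = _envelope(h, maxima)
        lower = _envelope(h, minima)
        mean = 0.5 * (upper + lower)
        h_new = h - mean
        denom = np.sum(h * h)
        if denom == 0:
            return h_new
        sd = float(np.sum(mean * mean) / denom)
        h = h_new
        if sd < SIFT_SD_TOL:
            break
    return h


def emd_decompose(x: np.ndarray, max_imfs: int = DEFAULT_MAX_IMFS) -> EmdDecomposition:
    """Empirical mode decomposition of a real record.

    Successively sifts IMFs from the record until the remainder has fewer
    than two maxima or two minima (a monotone or trivial trend), or
    ``max_imfs`` components have been extracted.  The returned components
    satisfy the reconstruction identity ``sum(imfs) + residual == x``
    exactly up to floating-point rounding.

    A strictly monotone input yields zero IMFs and the input itself as the
    residual.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("record too short for EMD (need >= 8 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    residual = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        imf = _sift(residual)
        if imf is None:
            break
        imfs.append(imf)
        residual = residual - imf
    return EmdDecomposition(imfs=imfs, residual=residual)


def classify_and_filter(dec: EmdDecomposition, f0: int) -> np.ndarray:
    """Drop high-frequency IMFs and rebuild the record.

    An IMF with zero-crossing count ``f_i >= 3 * f0`` is removed (the
    boundary case ``f_i == 3 * f0`` counts as high-frequency); the output
    is the residual plus all surviving IMFs.
    """
    if f0 < 0:
        raise ValueError("f0 must be non-negative")
    out = dec.residual.copy()
    for imf in dec.imfs:
        if zero_crossing_count(imf) < HF_RATIO * f0:
            out += imf
    return out


def emd_denoise(x: np.ndarray, max_imfs: int = DEFAULT_MAX_IMFS) -> np.ndarray:
    """EMD denoising of a real record: decompose, reject by 3*f0, rebuild.

    The zero-crossing reference ``f_0`` is counted on the raw input record.
    """
    x = np.asarray(x, dtype=float)
    dec = emd_decompose(x, max_imfs=max_imfs)
    return classify_and_filter(dec, zero_crossing_count(x))


def dwt_denoise(
    x: np.ndarray,
    wavelet: str = "db10",
    levels: int = 3,
    threshold: float | None = None,
    threshold_levels: int = 2,
) -> np.ndarray:
    """Wavelet denoising of a real record.

    Parameters
    ----------
    x
        Real record; must be long enough for one db10 decomposition step.
    wavelet, levels
        Decomposition wavelet and depth.  db10 at 3 levels keeps the lowest
        eighth of the band as the approximation — exactly the band that
        carries the beat tone.
    threshold
        Soft threshold applied to the detail coefficients.  ``None``
        (default) uses the universal threshold ``sigma_hat * sqrt(2 ln n)``
        with ``sigma_hat = MAD(level-1 details) / 0.6745``; ``0`` disables
        shrinkage, in which case the reconstruction equals the input.
    threshold_levels
        How many of the finest detail levels to shrink.  The default (2 of
        3) thresholds the detail bands covering the upper half of the
        spectrum, where the acquisition noise lives, and leaves the
        coarsest detail band — which borders the beat tone — untouched, so
        the low-frequency spectrum of the reconstruction stays on top of
        the clean signal's.
    """
    x = np.asarray(x, dtype=float)
    w = pywt.Wavelet(wavelet)
    if len(x) < w.dec_len:
        raise ValueError(
            f"record of length {len(x)} too short for {wavelet} (filter "
            f"length {w.dec_len})"
        )
    with warnings.catch_warnings():
        # short records trigger a boundary-effect warning at level 3;
        # symmetric extension keeps the transform invertible regardless
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, w, mode="symmetric", level=levels)
    if threshold is None:
        d1 = coeffs[-1]
        sigma = float(np.median(np.abs(d1))) / 0.6745 if d1.size else 0.0
        threshold = sigma * math.sqrt(2.0 * math.log(max(len(x), 2)))
    if threshold > 0:
        # coeffs[-1] is the finest detail level; shrink the finest
        # threshold_levels bands only
        first = max(1, len(coeffs) - threshold_levels)
        coeffs = coeffs[:first] + [
            pywt.threshold(c, threshold, mode="soft") for c in coeffs[first:]
        ]
    out = pywt.waverec(coeffs, w, mode="symmetric")
    return out[: len(x)]


def denoise_complex(x: np.ndarray, method: str = "dwt", **kwargs) -> np.ndarray:
    """Denoise a complex record part-wise.

    ``method`` is one of ``"emd"``, ``"dwt"`` or ``"none"``; the chosen
    real-signal denoiser runs on the real and imaginary parts independently
    and the parts are recombined.
    """
    x = np.asarray(x)
    if method == "none":
        return x.astype(np.complex128, copy=True)
    if method == "emd":
        fn = emd_denoise
    elif method == "dwt":
        fn = dwt_denoise
    else:
        raise ValueError(f"unknown denoising method {method!r}; use emd|dwt|none")
    return fn(np.asarray(x.real, dtype=float), **kwargs) + 1j * fn(
        np.asarray(x.imag, dtype=float), **kwargs
    )
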