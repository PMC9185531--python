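"""Complex CWT scalogram tensors — the classifier's input encoding.

A complex beat record is analysed with an analytic (complex Morlet)
wavelet twice: once directly, which responds to the counterclockwise
(positive-frequency) content, and once on the conjugated record, which is
the standard realisation of the negative-scale / clockwise half of the
transform.  The two complex matrices are unpacked into four real pages

    page 1: Re CWT(+),  page 2: Im CWT(+),
    page 3: Re CWT(-),  page 4: Im CWT(-),

stacked into an ``(n_scales, N, 4)`` tensor and zero-mean normalised
(global mean subtraction — no variance scaling by default).  The tensor
preserves both the amplitude and the phase of the echo, which is what lets
a classifier separate concentration classes across power-cycle drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

#: analytic Morlet with bandwidth 1.5 and centre frequency 1.0
DEFAULT_WAVELET = "cmor1.5-1.0"
DEFAULT_N_SCALES = 32
#: scale span: centre-frequency/scale covers ~0.5 down to ~0.025 cycles per
#: sample, bracketing the beat tone in the lowest eighth of the band
DEFAULT_SCALE_RANGE = (2.0, 40.0)


@dataclass
class ScalogramTensor:
    """Four-page real CWT tensor with its normalisation state."""

    values: np.ndarray  # (n_scales, n_time, 4)
    scales: np.ndarray
    normalization_state: str = "raw"

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[2] != 4:
            raise ValueError("tensor must have shape (n_scales, n_time, 4)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def default_scales(n_scales: int = DEFAULT_N_SCALES) -> np.ndarray:
    lo, hi = DEFAULT_SCALE_RANGE
    return np.geomspace(lo, hi, n_scales)


def cwt_complex(
    x: np.ndarray,
    scales: np.ndarray | int = DEFAULT_N_SCALES,
    wavelet: str = DEFAULT_WAVELET,
) -> tuple[np.ndarray, np.ndarray]:
    """Positive- and negative-scale CWT of a complex record.

    Returns two ``(n_scales, len(x))`` complex matrices.  The positive-
    scale matrix is the analytic-wavelet transform of the record itself and
    responds to counterclockwise (positive-frequency) tones; the negative-
    scale matrix is the transform of the conjugated record and responds to
    clockwise tones.
    """
    x = np.asarray(x, dtype=np.complex128)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("need a one-dimensional record of at least 8 samples")
    if isinstance(scales, (int, np.integer)):
        if scales < 4:
            raise ValueError("need at least 4 scales")
        scales = default_scales(int(scales))
    scales = np.asarray(scales, dtype=float)
    pos, _ = pywt.cwt(x, scales, wavelet)
    neg, _ = pywt.cwt(np.conj(x), scales, wavelet)
    return pos, neg


def build_input_tensor(pos: np.ndarray, neg: np.ndarray) -> ScalogramTensor:
    """Stack the four real pages and zero-mean normalise.

    Page order: Re(+), Im(+), Re(-), Im(-).  The global mean over all
    entries is subtracted, so the returned tensor's mean is zero.
    """
    pos = np.asarray(pos)
    neg = np.asarray(neg)
    if pos.shape != neg.shape:
        raise ValueError(
            f"positive/negative scale matrices differ in shape: "
            f"{pos.shape} vs {neg.shape}"
        )
    pages = np.stack([pos.real, pos.imag, neg.real, neg.imag], axis=-1)
    pages = pages - pages.mean()
    return ScalogramTensor(
        values=pages,
        scales=np.arange(pos.shape[0], dtype=float),
        normalization_state="zero_mean",
    )


def scalogram_tensor(
    x: np.ndarray,
    n_scales: int = DEFAULT_N_SCALES,
    wavelet: str = DEFAULT_WAVELET,
    scale_variance: bool = False,
) -> ScalogramTensor:
    """One-call encoding of a complex record into the network input tensor.

    ``scale_variance=True`` additionally divides by the global standard
    deviation after mean removal (off by default).
    """
    pos, neg = cwt_complex(x, n_scales, wavelet)
    tensor = build_input_tensor(pos, neg)
    if scale_variance:
        sd = tensor.values.std()
        if sd > 0:
            tensor.values = tensor.values / sd
    return tensor


def batch_tensors(
    records: list[np.ndarray],
    n_scales: int = DEFAULT_N_SCALES,
    wavelet: str = DEFAULT_WAVELET,
) -> np.ndarray:
    """Encode a list of complex records into a (B, n_scales, N, 4) array."""
    return np.stack(
        [scalogram_tensor(r, n_scales, wavelet).values for r in records]
    )
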