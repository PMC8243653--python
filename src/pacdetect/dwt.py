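"""Undecimated quadratic-spline dyadic wavelet transform, scale 4.

The transform is realized as an a-trous filter bank: the classic
quadratic-spline pair used throughout the wavelet ECG literature
(low-pass taps proportional to [1, 3, 3, 1]/8, high-pass proportional to
[2, -2]) cascaded with zero-insertion up to scale 2^4, with no
downsampling so every scale keeps the input sampling rate.  Only the
scale-4 detail signal (W4) is exposed; it serves as the second signal
version for the morphology features.

Tap normalization differs across published variants; any positive gain
is immaterial to normalized cross-correlation features, so gain is fixed
at 1 here.  The implementation is calibrated to a 250 Hz input.
"""

from __future__ import annotations

from functools import lru_cache, reduce
from typing import List

import numpy as np

__all__ = ["LOWPASS_TAPS", "HIGHPASS_TAPS", "atrous_filters", "equivalent_fir", "group_delay_samples", "w4_transform"]

LOWPASS_TAPS = np.array([1.0, 3.0, 3.0, 1.0]) / 8.0
HIGHPASS_TAPS = np.array([2.0, -2.0])

REQUIRED_FS = 250.0
SCALE = 4


def _upsample(taps: np.ndarray, factor: int) -> np.ndarray:
    """A-trous zero insertion: place taps ``factor`` samples apart."""
    if factor == 1:
        return taps.copy()
    out = np.zeros((taps.size - 1) * factor + 1)
    out[::factor] = taps
    return out


@lru_cache(maxsize=4)
def _filter_bank(scale: int):
    filters: List[np.ndarray] = [
        _upsample(LOWPASS_TAPS, 2**j) for j in range(scale - 1)
    ]
    filters.append(_upsample(HIGHPASS_TAPS, 2 ** (scale - 1)))
    return tuple(f.copy() for f in filters)


def atrous_filters(scale: int = SCALE):
    """The cascade producing the scale-``scale`` detail signal."""
    return [f.copy() for f in _filter_bank(scale)]


def equivalent_fir(scale: int = SCALE) -> np.ndarray:
    """Single FIR whose convolution equals the cascaded bank (oracle/docs)."""
    return reduce(np.convolve, _filter_bank(scale))


def group_delay_samples(scale: int = SCALE) -> int:
    """Integer group delay of the cascade; half-sample residue -> toward zero."""
    exact = sum((f.size - 1) / 2.0 for f in _filter_bank(scale))
    return int(exact)  # truncation == toward zero for positive delay


def w4_transform(lead, fs: float = REQUIRED_FS) -> np.ndarray:
    """Scale-4 detail of the undecimated quadratic-spline transform.

    Linear, length-preserving, group-delay compensated so a QRS complex
    and its W4 signature share the same R-sample reference.  Boundary
    handling is mirror extension; only samples within the filter support
    of the record edges are affected (all inside the 40-beat trim).
    """
    if fs != REQUIRED_FS:
        raise ValueError(
            f"w4_transform is calibrated to {REQUIRED_FS:g} Hz; resample first (got fs={fs})"
        )
    x = np.asarray(lead, dtype=float)
    n = x.size
    support = equivalent_fir(SCALE).size - 1
    if n < 2:
        return np.zeros(n)
    pad = min(support, n - 1)
    z = np.pad(x, pad, mode="reflect")
    for taps in _filter_bank(SCALE):
        z = np.convolve(z, taps, mode="full")
    start = pad + group_delay_samples(SCALE)
    return z[start : start + n]
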