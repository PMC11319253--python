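"""Discrete wavelet transform features (the comparison branch).

A dyadic DWT (scale base a0 = 2, translation base b0 = 1) decomposes each
epoch into ``levels`` detail bands plus one approximation band.  With an
orthogonal wavelet and periodized boundary handling the transform is a
change of orthonormal basis: the total coefficient count equals the input
length, reconstruction is exact, and energy is conserved.  The feature
vector concatenates all subbands coarse→fine:

    [cA_L, cD_L, cD_{L−1}, ..., cD_1]

so the first block covers (0, fs/2^{L+1}) Hz, the next (fs/2^{L+1},
fs/2^{L}) Hz, and so on up to (fs/4, fs/2).  Defaults: db4, 5 levels, so at
fs = 173.61 Hz the subband edges straddle the 3–40 Hz analysis band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt


@dataclass
class WaveletDecomposition:
    """Per-scale DWT coefficients, ordered coarse→fine.

    ``coefficients[0]`` is the level-``levels`` approximation band;
    ``coefficients[1:]`` are detail bands from coarsest (level ``levels``)
    to finest (level 1).
    """

    coefficients: list[np.ndarray]
    wavelet_name: str
    levels: int
    mode: str
    input_len: int
    a0: float = 2.0
    b0: float = 1.0

    @property
    def total_coefficients(self) -> int:
        return int(sum(c.size for c in self.coefficients))


def dwt_decompose(
    epoch: np.ndarray,
    levels: int = 5,
    wavelet: str = "db4",
    mode: str = "periodization",
) -> WaveletDecomposition:
    """Dyadic DWT of one epoch into ``levels`` detail bands + approximation."""
    x = np.asarray(epoch, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("epoch must be 1-D")
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    if 2**levels > x.size:
        max_l = max(int(np.log2(x.size)), 0)
        raise ValueError(
            f"{levels} levels need at least 2^{levels} samples; epoch has "
            f"{x.size} (maximum {max_l} levels)"
        )
    coeffs = pywt.wavedec(x, wavelet, mode=mode, level=levels)
    return WaveletDecomposition(
        coefficients=[np.asarray(c) for c in coeffs],
        wavelet_name=wavelet,
        levels=levels,
        mode=mode,
        input_len=x.size,
    )


def dwt_reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Inverse DWT; exact to numerical precision for orthogonal wavelets."""
    x = pywt.waverec(dec.coefficients, dec.wavelet_name, mode=dec.mode)
    return x[: dec.input_len]


def dwt_feature(
    epoch: np.ndarray,
    levels: int = 5,
    wavelet: str = "db4",
    mode: str = "periodization",
) -> np.ndarray:
    """Concatenated subband coefficients, coarse→fine, fixed length.

    With the periodized orthogonal default the feature length equals the
    epoch length and the feature energy equals the epoch energy.
    """
    dec = dwt_decompose(epoch, levels=levels, wavelet=wavelet, mode=mode)
    return np.concatenate(dec.coefficients)


def subband_ranges(fs: float, levels: int) -> list[tuple[float, float]]:
    """Nominal (low, high) Hz range of each subband, in feature order."""
    ny = fs / 2.0
    out = [(0.0, ny / 2**levels)]
    for lev in range(levels, 0, -1):
        out.append((ny / 2**lev, ny / 2 ** (lev - 1)))
    return out
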