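"""FFT magnitude features: DFT coefficients reshaped into an m×n matrix.

For an epoch x(n), n = 0..N−1, the DFT coefficients are

    X_k = Σ_{n=0}^{N−1} x(n) · exp(−i 2π k n / N),   k = 0..N−1,

their magnitudes A_k = |X_k| are taken, and the full-length magnitude
vector is laid out row-major into an m×n matrix (m·n = N): row 1 holds
A_1..A_n, row 2 holds A_{n+1}..A_{2n}, and so on (1-based).  The full
spectrum is kept, including the redundant conjugate-symmetric half, so the
reshape is exact for any factorisation of N.  For 1,024-sample epochs the
default is the square 32×32 matrix.
"""

from __future__ import annotations

import numpy as np


def dft_coefficients(epoch: np.ndarray) -> np.ndarray:
    """Complex DFT coefficients X_0..X_{N−1} of a real epoch."""
    x = np.asarray(epoch, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("epoch must be a non-empty 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("epoch contains non-finite samples")
    return np.fft.fft(x)


def magnitudes(X: np.ndarray) -> np.ndarray:
    """Magnitudes A_k = |X_k| of the DFT coefficients."""
    return np.abs(np.asarray(X))


def to_matrix(A: np.ndarray, m: int, n: int) -> np.ndarray:
    """Reshape the magnitude vector row-major into an m×n matrix.

    Entry (i, j) equals A_{(i−1)·n + j} in 1-based indexing.
    """
    A = np.asarray(A)
    if m < 1 or n < 1 or m * n != A.size:
        raise ValueError(
            f"cannot reshape spectrum of length {A.size} into {m}×{n} "
            f"(m·n = {m * n})"
        )
    return A.reshape(m, n)


def fft_feature(epoch: np.ndarray, m: int = 32, n: int = 32) -> np.ndarray:
    """The m×n FFT magnitude matrix of one epoch."""
    return to_matrix(magnitudes(dft_coefficients(epoch)), m, n)
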