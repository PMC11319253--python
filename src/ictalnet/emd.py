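"""Empirical mode decomposition: sifting a signal into intrinsic mode functions.

EMD decomposes a signal x(n) into a small set of band-limited intrinsic
mode functions (IMFs) plus a residue r, with

    x(n) = Σ_k imf_k(n) + r(n)          (exact by construction)

Each IMF must (1) have extrema and zero-crossing counts equal or differing
by one, and (2) have an approximately zero mean envelope everywhere.  One
sifting pass builds cubic-spline envelopes through the local maxima and
minima, subtracts their pointwise mean, and repeats until the candidate
satisfies the IMF conditions; the extracted IMF is subtracted and sifting
restarts on the remainder until it is monotonic (or nearly so).  IMFs come
out fine-to-coarse: imf_1 carries the highest-frequency content and the
residue the lowest.

Numerical choices (see docs/methods.md): the IMF acceptance test combines
the counting condition with a mean-envelope smallness test
‖m‖₂/‖h‖₂ < 0.05; sifting is capped at 100 passes per IMF; spline
envelopes mirror the two nearest extrema beyond each signal edge to damp
end swings; the midpoint of a plateau counts as a single extremum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

#: Default mean-envelope smallness threshold, ‖m‖₂/‖h‖₂.
MEAN_RATIO_TOL = 0.05

#: Default cap on sifting passes per IMF.
MAX_SIFT_ITER = 100


@dataclass
class IMFSet:
    """Ordered IMFs (fine→coarse), the residue, and per-IMF sift counts."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    n_sift_iterations: list[int] = field(default_factory=list)
    capped: list[bool] = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """Σ imfs + residue; equals the input to numerical precision."""
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def _compress_plateaus(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse runs of equal consecutive values to their midpoint index."""
    n = x.size
    starts = np.flatnonzero(np.r_[True, x[1:] != x[:-1]])
    ends = np.r_[starts[1:], n]  # exclusive
    mid = (starts + ends - 1) // 2
    return mid, x[starts]


def find_extrema(
    x: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Strict interior local extrema by three-point comparison.

    Returns ``(max_idx, max_val, min_idx, min_val)``.  A plateau (run of
    equal values) counts as a single extremum at its midpoint sample.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D signal of length >= 3")
    idx, v = _compress_plateaus(x)
    if v.size < 3:
        empty = np.array([], dtype=int), np.array([])
        return empty[0], empty[1], empty[0].copy(), empty[1].copy()
    left, mid, right = v[:-2], v[1:-1], v[2:]
    is_max = (mid > left) & (mid > right)
    is_min = (mid < left) & (mid < right)
    interior = idx[1:-1]
    return interior[is_max], mid[is_max], interior[is_min], mid[is_min]


def zero_crossings(x: np.ndarray) -> int:
    """Count sign changes, ignoring exact zeros between them."""
    s = np.sign(np.asarray(x, dtype=np.float64))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s) != 0))


def _mirrored_spline(
    idx: np.ndarray, val: np.ndarray, n: int
) -> np.ndarray:
    """Cubic spline through extrema, mirroring two extrema beyond each edge."""
    k = min(2, idx.size)
    left_x = -idx[:k][::-1]
    left_y = val[:k][::-1]
    right_x = 2 * (n - 1) - idx[-k:][::-1]
    right_y = val[-k:][::-1]
    xs = np.concatenate([left_x, idx, right_x])
    ys = np.concatenate([left_y, val, right_y])
    xs, keep = np.unique(xs, return_index=True)
    ys = ys[keep]
    if xs.size < 2:
        return np.full(n, ys[0] if ys.size else 0.0)
    if xs.size < 4:  # too few knots for a cubic; fall back to linear
        return np.interp(np.arange(n), xs, ys)
    return CubicSpline(xs, ys)(np.arange(n))


def envelopes(
    x: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Upper/lower cubic-spline envelopes and their pointwise mean.

    Returns ``(e_max, e_min, m)`` with ``m = (e_max + e_min) / 2``, or
    ``None`` when the signal has fewer than two maxima or two minima and
    must be treated as a residue (monotonic-like) by the caller.
    """
    x = np.asarray(x, dtype=np.float64)
    max_i, max_v, min_i, min_v = find_extrema(x)
    if max_i.size < 2 or min_i.size < 2:
        return None
    n = x.size
    e_max = _mirrored_spline(max_i, max_v, n)
    e_min = _mirrored_spline(min_i, min_v, n)
    return e_max, e_min, (e_max + e_min) / 2.0


def is_imf(x: np.ndarray) -> bool:
    """The counting half of the IMF condition: |#extrema − #zc| ≤ 1."""
    max_i, _, min_i, _ = find_extrema(x)
    return abs((max_i.size + min_i.size) - zero_crossings(x)) <= 1


def sift(
    x: np.ndarray,
    mean_ratio_tol: float = MEAN_RATIO_TOL,
    max_iter: int = MAX_SIFT_ITER,
) -> tuple[np.ndarray, int, bool]:
    """Extract one IMF by iterative envelope-mean subtraction.

    Returns ``(imf, n_iterations, capped)``.  ``capped`` is True when the
    iteration cap was reached before the stopping rule was met; the current
    candidate is returned with a warning in that case.
    """
    h = np.asarray(x, dtype=np.float64).copy()
    for it in range(1, max_iter + 1):
        env = envelopes(h)
        if env is None:
            # no further sifting possible; caller treats h as (near-)IMF
            return h, it, False
        _, _, m = env
        hn = np.linalg.norm(h)
        if is_imf(h) and (hn == 0 or np.linalg.norm(m) / hn < mean_ratio_tol):
            return h, it, False
        h = h - m
    warnings.warn(
        f"sifting cap of {max_iter} iterations reached; returning current "
        "candidate",
        stacklevel=2,
    )
    return h, max_iter, True


def _is_residue(x: np.ndarray) -> bool:
    """Monotonic-like: fewer than two maxima or two minima (cannot envelope)."""
    if x.size < 3:
        return True
    max_i, _, min_i, _ = find_extrema(x)
    return max_i.size < 2 or min_i.size < 2


def decompose(
    x: np.ndarray,
    max_imfs: int = 10,
    mean_ratio_tol: float = MEAN_RATIO_TOL,
    max_iter: int = MAX_SIFT_ITER,
) -> IMFSet:
    """Full EMD: extract IMFs fine-to-coarse until the residue is monotonic.

    A strictly monotonic input yields zero IMFs and residue equal to the
    input.  The reconstruction identity Σ imfs + residue == x holds to
    numerical precision by construction.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("need a 1-D signal of length >= 8")
    r = x.copy()
    imfs: list[np.ndarray] = []
    iters: list[int] = []
    capped: list[bool] = []
    while len(imfs) < max_imfs and not _is_residue(r):
        imf, nit, cap = sift(r, mean_ratio_tol=mean_ratio_tol, max_iter=max_iter)
        if not np.any(imf):  # degenerate: no progress possible
            break
        imfs.append(imf)
        iters.append(nit)
        capped.append(cap)
        r = r - imf
    return IMFSet(imfs=imfs, residue=r, n_sift_iterations=iters, capped=capped)


def emd_feature(
    epoch: np.ndarray, n_channels: int = 5, max_imfs: int = 10
) -> np.ndarray:
    """First ``n_channels`` IMFs stacked as channels, shape (5, epoch_len).

    The ictal signature concentrates in the first five IMFs, so those are
    the feature; signals yielding fewer IMFs get all-zero trailing channels.
    """
    x = np.asarray(epoch, dtype=np.float64)
    imf_set = decompose(x, max_imfs=max_imfs)
    out = np.zeros((n_channels, x.size))
    for i, imf in enumerate(imf_set.imfs[:n_channels]):
        out[i] = imf
    return out
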