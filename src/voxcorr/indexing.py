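"""Bijective maps between voxel pairs and condensed-array positions.

The N×N Pearson correlation matrix of N voxels is symmetric with a unit
diagonal, so all distinct coefficients live in its strict upper triangle:
N(N−1)/2 values. This module defines the canonical row-major ordering of
those values in a flat ("condensed") array —

    (0,1), (0,2), ..., (0,N−1), (1,2), ..., (N−2,N−1)

— and exact integer maps in both directions. The forward map is the closed
form

    k = i·n − i(i+1)/2 + j − i − 1,   0 ≤ i < j < n,

so the first n−1 positions hold voxel 0's correlations, the next n−2 hold
voxel 1's, and so on. The inverse is computed with an exact integer square
root plus a bounded correction step, so it never mis-rounds for large k
(floating-point square roots do, far below the n ≈ 10^6 scales these arrays
reach in voxel-level connectivity).

All functions accept Python ints or integer ndarrays and are exact in
64-bit arithmetic for n up to 10^7.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["triangle_size", "pair_to_linear", "linear_to_pair", "row_start"]


def triangle_size(n: int) -> int:
    """Number of distinct voxel pairs among ``n`` voxels: n(n−1)/2.

    Exact integer arithmetic; for n = 100 000 this is 4 999 950 000,
    which overflows 32-bit counters, so everything downstream uses
    64-bit (or Python-int) indices.
    """
    n = _check_n(n)
    return n * (n - 1) // 2


def row_start(i, n):
    """Condensed position of pair (i, i+1): start of row ``i`` of the triangle.

    Vectorized over ``i``.
    """
    return i * n - i * (i + 1) // 2


def pair_to_linear(i, j, n):
    """Map voxel pair(s) (i, j) with i < j to condensed position(s) k.

    Parameters
    ----------
    i, j : int or integer array
        0-based voxel indices; requires 0 ≤ i < j < n elementwise. Callers
        wanting symmetric lookup must canonicalize (min, max) first.
    n : int
        Total voxel count.

    Returns
    -------
    int or int64 array
        k = i·n − i(i+1)/2 + j − i − 1, in [0, n(n−1)/2).
    """
    n = _check_n(n)
    if np.isscalar(i) and np.isscalar(j):
        i, j = int(i), int(j)
        if not (0 <= i < j < n):
            raise ValueError(
                f"pair ({i}, {j}) out of range: need 0 <= i < j < n with n={n}"
            )
        return row_start(i, n) + j - i - 1
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    if np.any(i < 0) or np.any(i >= j) or np.any(j >= n):
        raise ValueError(f"pair indices out of range: need 0 <= i < j < n with n={n}")
    return row_start(i, n) + j - i - 1


def linear_to_pair(k, n):
    """Invert :func:`pair_to_linear`: condensed position(s) k → pair(s) (i, j).

    Exact for every valid k at least up to n = 10^6: the row index is
    recovered from the integer square root of the discriminant of the
    triangular-number equation, counting from the *end* of the array
    (where row lengths are 1, 2, 3, ...), then nudged by a correction
    loop that terminates in at most one step.
    """
    n = _check_n(n)
    t = n * (n - 1) // 2
    if np.isscalar(k):
        k = int(k)
        if not (0 <= k < t):
            raise ValueError(f"linear index {k} out of range [0, {t}) for n={n}")
        # rev = position counted from the end; row i (from the top) is the
        # (n−1−i)-th row from the bottom and holds pairs with
        # rev in [m(m−1)/2, m(m+1)/2) where m = n−1−i.
        rev = t - 1 - k
        s = math.isqrt(8 * rev + 1)
        i = n - 2 - (s - 1) // 2
        # bounded correction (no-op when isqrt is exact, which it is here;
        # kept so the bijection property, not the algebra, is the contract)
        while i > 0 and k < row_start(i, n):
            i -= 1
        while i < n - 2 and k >= row_start(i + 1, n):
            i += 1
        j = k - row_start(i, n) + i + 1
        return i, j

    k = np.asarray(k, dtype=np.int64)
    if k.size and (k.min() < 0 or k.max() >= t):
        raise ValueError(f"linear index out of range [0, {t}) for n={n}")
    rev = t - 1 - k
    d = 8 * rev + 1
    s = np.sqrt(d.astype(np.float64)).astype(np.int64)
    # repair float sqrt rounding so s = isqrt(d) exactly
    s -= (s * s > d).astype(np.int64)
    s += ((s + 1) * (s + 1) <= d).astype(np.int64)
    i = n - 2 - (s - 1) // 2
    lo = row_start(i, n)
    over = k < lo
    if np.any(over):
        i = np.where(over, i - 1, i)
        lo = row_start(i, n)
    under = k >= lo + (n - 1 - i)
    if np.any(under):
        i = np.where(under, i + 1, i)
        lo = row_start(i, n)
    j = k - lo + i + 1
    return i, j


def _check_n(n) -> int:
    n = int(n)
    if n < 0:
        raise ValueError(f"voxel count must be non-negative, got {n}")
    return n
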