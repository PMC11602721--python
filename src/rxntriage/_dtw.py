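"""Banded dynamic time warping with absolute-difference local cost.

Classic DTW dynamic program (symmetric step pattern: match, insertion,
deletion all weight 1) with an optional Sakoe-Chiba band. The full cumulative
matrix is kept so the optimal warping-path length can be recovered; the
normalized distance (distance / path length) is what the decision thresholds
operate on, making them grid-length independent.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["dtw"]


@njit(cache=True)
def _dtw_matrix(a: np.ndarray, b: np.ndarray, band: int) -> np.ndarray:
    n, m = a.shape[0], b.shape[0]
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        # band is defined on normalized index difference so unequal lengths work
        centre = int(round(i * m / n))
        jlo = max(1, centre - band)
        jhi = min(m, centre + band)
        for j in range(jlo, jhi + 1):
            c = abs(a[i - 1] - b[j - 1])
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = c + best
    return D


@njit(cache=True)
def _path_length(D: np.ndarray) -> int:
    i, j = D.shape[0] - 1, D.shape[1] - 1
    length = 1
    while i > 1 or j > 1:
        diag = D[i - 1, j - 1] if (i > 1 and j > 1) else np.inf
        up = D[i - 1, j] if i > 1 else np.inf
        left = D[i, j - 1] if j > 1 else np.inf
        if diag <= up and diag <= left:
            i -= 1
            j -= 1
        elif up <= left:
            i -= 1
        else:
            j -= 1
        length += 1
    return length


def dtw(a: np.ndarray, b: np.ndarray, band: int | None = None) -> tuple[float, int]:
    """DTW distance and optimal warping-path length between two sequences.

    ``band`` is the Sakoe-Chiba radius in points (None = unconstrained).
    Raises ``ValueError`` on empty input or when the band is too narrow to
    admit any monotone path.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot compute DTW of an empty sequence")
    if band is None:
        band = max(a.size, b.size)
    if band < 0:
        raise ValueError(f"band must be >= 0, got {band}")
    band = max(band, abs(a.size - b.size), 1)
    D = _dtw_matrix(a, b, band)
    dist = D[-1, -1]
    if not np.isfinite(dist):
        raise ValueError("band too narrow: no admissible warping path")
    return float(dist), int(_path_length(D))
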