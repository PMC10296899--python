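"""Numba kernels for the O(N^2) template-matching loops.

Both entropies compare all pairs of m-point templates under the Chebyshev
(max-norm) distance; the loops are quadratic in series length and are the
only hot spots of the package, so they are jitted.  Template start indices
run over 0..N-m-1 for both the m- and (m+1)-point counts (the
Richman–Moorman convention), and self-matches are excluded.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LN2 = 0.6931471805599453


@njit(fastmath=False)
def _sampen_counts_m2(x: np.ndarray, r: float) -> tuple[int, int]:
    """m=2 specialization of the pair counts (unrolled inner comparisons)."""
    n = x.shape[0]
    nt = n - 2
    a = 0
    b = 0
    for i in range(nt - 1):
        x0 = x[i]
        x1 = x[i + 1]
        x2 = x[i + 2]
        for j in range(i + 1, nt):
            if abs(x0 - x[j]) > r:
                continue
            if abs(x1 - x[j + 1]) > r:
                continue
            b += 1
            if abs(x2 - x[j + 2]) <= r:
                a += 1
    return a, b


@njit(fastmath=False)
def _sampen_counts_generic(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    n = x.shape[0]
    nt = n - m
    a = 0
    b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Counts (A, B): template pairs matching within r for m+1 and m points."""
    if m == 2:
        return _sampen_counts_m2(x, r)
    return _sampen_counts_generic(x, m, r)


@njit(fastmath=False)
def fuzzy_phi(x: np.ndarray, m: int, nt: int, r: float, n_exp: float) -> float:
    """Mean fuzzy membership exp(-ln2*(d/r)^n) over template pairs.

    Templates are baseline-removed (each m-point template minus its own
    mean) before the Chebyshev distance is taken; ``nt`` template start
    positions are used so the m- and (m+1)-point passes share the same pair
    population.
    """
    mu = np.empty(nt)
    for i in range(nt):
        s = 0.0
        for k in range(m):
            s += x[i + k]
        mu[i] = s / m
    total = 0.0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            d = 0.0
            for k in range(m):
                diff = abs((x[i + k] - mu[i]) - (x[j + k] - mu[j]))
                if diff > d:
                    d = diff
            total += np.exp(-LN2 * (d / r) ** n_exp)
    return total / (nt * (nt - 1) / 2.0)
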