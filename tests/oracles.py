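"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths (and, where practical, the library
calls) used by the package: explicit O(N^2) DFT summation, sort-based
percentiles with hand-written linear interpolation, loop-based moments and
crossing counts, and brute-force window-start enumeration.
"""

from __future__ import annotations

import cmath
import math

import numpy as np


def naive_dft_amplitude(x) -> np.ndarray:
    """|DFT(x - mean)| over bins 0..N/2 by explicit summation."""
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    xp = [v - mean for v in x]
    out = []
    for xi in range(n // 2 + 1):
        acc = 0j
        for k in range(n):
            acc += xp[k] * cmath.exp(-2j * math.pi * xi * k / n)
        out.append(abs(acc))
    return np.asarray(out)


def naive_two_sided_power(x) -> float:
    """sum over all N bins of |DFT(x - mean)|^2 (for the Parseval check)."""
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    xp = [v - mean for v in x]
    total = 0.0
    for xi in range(n):
        acc = 0j
        for k in range(n):
            acc += xp[k] * cmath.exp(-2j * math.pi * xi * k / n)
        total += abs(acc) ** 2
    return total


def naive_percentile(x, q: float) -> float:
    """Linear interpolation between order statistics at rank q/100*(n-1)."""
    s = sorted(map(float, x))
    rank = q / 100.0 * (len(s) - 1)
    lo = int(math.floor(rank))
    hi = min(lo + 1, len(s) - 1)
    frac = rank - lo
    return s[lo] + frac * (s[hi] - s[lo])


def naive_time_features(x) -> np.ndarray:
    """The 20 time-domain statistics via explicit loops and sorting."""
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    centered = [v - mean for v in x]
    m2 = sum(v ** 2 for v in centered) / n
    m3 = sum(v ** 3 for v in centered) / n
    m4 = sum(v ** 4 for v in centered) / n
    std = math.sqrt(m2)
    skew = m3 / m2 ** 1.5 if m2 > 0 else 0.0
    kurt = m4 / m2 ** 2 if m2 > 0 else 0.0
    pct = [naive_percentile(x, q)
           for q in (0, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 95, 100)]
    rng = max(x) - min(x)
    rms = math.sqrt(sum(v ** 2 for v in x) / n)
    signs = [1 if v > 0 else -1 for v in centered if v != 0]
    zc = sum(1 for a, b in zip(signs, signs[1:]) if a != b)
    return np.asarray([mean, std, skew, kurt, *pct, rng, rms, float(zc)])


def naive_freq_features(xhat, n: int) -> np.ndarray:
    """energy, entropy, centroid, bandwidth, max-frequency via loops."""
    xhat = list(map(float, xhat))
    energy = sum(v ** 2 for v in xhat)
    total = sum(xhat)
    if total == 0:
        return np.asarray([0.0, 0.0, 0.0, 0.0, 0.0])
    p = [v / total for v in xhat]
    entropy = -sum(pi * math.log2(pi) for pi in p if pi > 0) / math.log2(n / 2)
    centroid = sum(xi * pi for xi, pi in enumerate(p))
    bandwidth = sum(abs(xi - centroid) * pi for xi, pi in enumerate(p))
    best = max(range(len(xhat)), key=lambda xi: (xhat[xi], -xi))
    return np.asarray([energy, entropy, centroid, bandwidth, float(best)])


def naive_window_features(x) -> np.ndarray:
    return np.concatenate([
        naive_time_features(x),
        naive_freq_features(naive_dft_amplitude(x), len(x)),
    ])


def brute_force_starts(t: int, n: int, overlap: float) -> list[int]:
    """All valid window starts: multiples of the step fitting fully in T."""
    step = max(int(round(n * (1 - overlap))), 1)
    starts = []
    s = 0
    while s + n <= t:
        starts.append(s)
        s += step
    return starts
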