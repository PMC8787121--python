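"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the code paths it checks: transforms
are direct O(N^4) summations, filters are explicit loops, rank statistics
are computed from first principles.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def naive_dft2(x: np.ndarray, inverse: bool = False) -> np.ndarray:
    """Direct double-sum 2-D DFT (O(N^4) arithmetic)."""
    x = np.asarray(x, dtype=complex)
    P, Q = x.shape
    sgn = 1j if inverse else -1j
    a = np.arange(P)
    b = np.arange(Q)
    out = np.zeros((P, Q), dtype=complex)
    for u in range(P):
        for v in range(Q):
            phase = np.exp(sgn * 2 * np.pi * (u * a[:, None] / P + v * b[None, :] / Q))
            out[u, v] = (x * phase).sum()
    return out / (P * Q) if inverse else out


def naive_box_filter(a: np.ndarray, k: int) -> np.ndarray:
    """Explicit k x k averaging with nearest-edge (clamped-index) padding."""
    P, Q = a.shape
    h = k // 2
    out = np.empty_like(a, dtype=float)
    for i in range(P):
        for j in range(Q):
            s = 0.0
            for di in range(-h, h + 1):
                for dj in range(-h, h + 1):
                    s += a[min(max(i + di, 0), P - 1), min(max(j + dj, 0), Q - 1)]
            out[i, j] = s / (k * k)
    return out


def naive_spectral_residual_map(pixels: np.ndarray, params) -> np.ndarray:
    """Full spectral-residual chain via direct DFT summation.

    Mirrors the documented pipeline (log-amplitude, gamma=1 stretch,
    box-filtered residual, inverse transform, squared magnitude, Gaussian
    smoothing) with naive transforms and filters.
    """
    assert params.gamma == 1.0, "oracle covers the published gamma=1 baseline"
    f = naive_dft2(pixels)
    amp = np.log(np.abs(f) + params.log_epsilon)
    phase = np.angle(f)
    residual = amp - naive_box_filter(amp, params.residual_filter_size)
    sal = np.abs(naive_dft2(np.exp(residual + 1j * phase), inverse=True)) ** 2
    # the Gaussian smoother is a shared primitive, not part of the
    # transform path under test
    return ndimage.gaussian_filter(sal, params.smooth_sigma, truncate=4.0,
                                   mode="nearest")


def naive_windowed_moments(pixels: np.ndarray, weights: np.ndarray,
                           box_correction: bool) -> tuple[np.ndarray, np.ndarray]:
    """Local weighted mean and std by explicit symmetric padding + loops."""
    k = weights.shape[0]
    h = k // 2
    padded = np.pad(pixels, h, mode="symmetric")
    P, Q = pixels.shape
    mean = np.empty((P, Q))
    std = np.empty((P, Q))
    n = k * k
    for i in range(P):
        for j in range(Q):
            patch = padded[i:i + k, j:j + k]
            m = (patch * weights).sum()
            var = ((patch - m) ** 2 * weights).sum()
            if box_correction and n > 1:
                var *= n / (n - 1.0)
            mean[i, j] = m
            std[i, j] = np.sqrt(max(var, 0.0))
    return mean, std


def rankdata_average(v: np.ndarray) -> np.ndarray:
    """Average ranks computed by explicit sorting and tie grouping."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(v.size, dtype=float)
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def brute_spearman(a, b) -> float:
    """Pearson correlation of average ranks, from the raw definition."""
    ra = rankdata_average(np.asarray(a, float))
    rb = rankdata_average(np.asarray(b, float))
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float((ra * rb).sum() / np.sqrt((ra**2).sum() * (rb**2).sum()))


def brute_kendall_tau_b(a, b) -> float:
    """Tau-b by O(n^2) pair enumeration with tie corrections."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = a.size
    conc = disc = ties_a = ties_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            da = np.sign(a[i] - a[j])
            db = np.sign(b[i] - b[j])
            if da == 0 and db == 0:
                continue
            if da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif da == db:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((conc + disc + ties_a) * (conc + disc + ties_b))
    return float((conc - disc) / denom)
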