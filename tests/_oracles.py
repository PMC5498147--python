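"""Independent brute-force oracles used by the tests.

These deliberately avoid the FFT/ndimage code paths of the package: the
correlation surface is a direct double loop over all integer lags, and the
projection oracle is a per-pixel Python loop.
"""

from __future__ import annotations

import numpy as np


def brute_force_correlation_surface(ref: np.ndarray, cur: np.ndarray) -> np.ndarray:
    """Direct cross-correlation of mean-subtracted images over all lags.

    Entry (i, j) corresponds to lag (dy, dx) = (i - h + 1, j - w + 1) and is
    sum over the overlap of cur[r, c] * ref[r - dy, c - dx].
    """
    a = np.asarray(cur, dtype=np.float64)
    b = np.asarray(ref, dtype=np.float64)
    a = a - a.mean()
    b = b - b.mean()
    h, w = a.shape
    out = np.zeros((2 * h - 1, 2 * w - 1))
    for i in range(2 * h - 1):
        dy = i - (h - 1)
        r0, r1 = max(0, dy), min(h, h + dy)
        for j in range(2 * w - 1):
            dx = j - (w - 1)
            c0, c1 = max(0, dx), min(w, w + dx)
            out[i, j] = np.sum(
                a[r0:r1, c0:c1] * b[r0 - dy : r1 - dy, c0 - dx : c1 - dx]
            )
    return out


def per_pixel_max_projection(stack_czhw: np.ndarray, channel: int) -> np.ndarray:
    """Exhaustive per-pixel max over z, written as explicit loops."""
    _, nz, h, w = stack_czhw.shape
    out = np.zeros((h, w), dtype=stack_czhw.dtype)
    for r in range(h):
        for c in range(w):
            m = stack_czhw[channel, 0, r, c]
            for z in range(1, nz):
                v = stack_czhw[channel, z, r, c]
                if v > m:
                    m = v
            out[r, c] = m
    return out


def smooth_texture(rng: np.random.Generator, shape=(64, 64), smooth: int = 2) -> np.ndarray:
    """Band-limited random texture (moving-average smoothed noise)."""
    img = rng.random(shape)
    if smooth > 1:
        k = np.ones((smooth, smooth)) / smooth**2
        from scipy.signal import convolve2d

        img = convolve2d(img, k, mode="same", boundary="wrap")
    return img
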