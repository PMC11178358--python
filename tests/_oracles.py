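"""Independent brute-force oracles used to pin the implementations.

Everything here is deliberately written as plain nested loops over pixels,
structurally unrelated to the vectorized implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_maxima_2d(img, min_distance, threshold_fraction):
    """Exhaustive greedy 2D maximum finding (accepted (y, x) set)."""
    img = np.asarray(img)
    h, w = img.shape
    cands = []
    for y in range(h):
        for x in range(w):
            v = img[y, x]
            strict = True
            for dy, dx in itertools.product((-1, 0, 1), repeat=2):
                if dy == dx == 0:
                    continue
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w and img[yy, xx] >= v:
                    strict = False
                    break
            if strict and v >= threshold_fraction * img.max():
                cands.append((v, y, x))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    accepted = []
    for v, y, x in cands:
        if all(
            math.hypot(y - ay, x - ax) >= min_distance for _, ay, ax in accepted
        ):
            accepted.append((v, y, x))
    return {(y, x) for _, y, x in accepted}


def brute_maxima_3d(img, min_sep_xy, min_sep_z, threshold_fraction):
    """Exhaustive greedy 3D maximum finding with anisotropic exclusion."""
    img = np.asarray(img)
    nz, ny, nx = img.shape
    cands = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = img[z, y, x]
                strict = True
                for dz, dy, dx in itertools.product((-1, 0, 1), repeat=3):
                    if dz == dy == dx == 0:
                        continue
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if (
                        0 <= zz < nz
                        and 0 <= yy < ny
                        and 0 <= xx < nx
                        and img[zz, yy, xx] >= v
                    ):
                        strict = False
                        break
                if strict and v >= threshold_fraction * img.max():
                    cands.append((v, z, y, x))
    cands.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    accepted = []
    for v, z, y, x in cands:
        ok = True
        for _, az, ay, ax in accepted:
            if math.hypot(y - ay, x - ax) < min_sep_xy and abs(z - az) < min_sep_z:
                ok = False
                break
        if ok:
            accepted.append((v, z, y, x))
    return {(z, y, x) for _, z, y, x in accepted}


def brute_fraction_counts(pos_a, pos_b):
    """Count marginals of a two-marker boolean table by explicit enumeration."""
    n_a = n_b = n_both = n_neither = 0
    for a, b in zip(pos_a, pos_b):
        if a:
            n_a += 1
        if b:
            n_b += 1
        if a and b:
            n_both += 1
        if (not a) and (not b):
            n_neither += 1
    return n_a, n_b, n_both, n_neither


def gaussian_kernel_2d(sigma, radius):
    """Explicitly sampled, normalized 2D Gaussian kernel."""
    ax = np.arange(-radius, radius + 1, dtype=float)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    k = np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
    return k / k.sum()


def cross_correlation_shift(a, b):
    """Integer shift (dy, dx) maximizing the circular cross-correlation of
    b against a, computed by direct FFT — used as a registration oracle."""
    fa = np.fft.fft2(a - a.mean())
    fb = np.fft.fft2(b - b.mean())
    cc = np.fft.ifft2(fa * np.conj(fb)).real
    dy, dx = np.unravel_index(np.argmax(cc), cc.shape)
    if dy > a.shape[0] // 2:
        dy -= a.shape[0]
    if dx > a.shape[1] // 2:
        dx -= a.shape[1]
    return dy, dx
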