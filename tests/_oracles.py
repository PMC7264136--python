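"""Independent brute-force oracles used to verify the pipeline stages.

Everything here is deliberately naive — per-pixel loops, explicit padding,
breadth-first floods, sort-based quantiles, direct quadrature — and shares
no code with the implementation it checks.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
from scipy.stats import norm, chi


def median3_oracle(img: np.ndarray) -> np.ndarray:
    """3x3 median, half-sample reflected borders, per-pixel sort."""
    padded = np.pad(img, 1, mode="symmetric")
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.sort(padded[i : i + 3, j : j + 3].ravel())[4]
    return out


def gaussian_oracle(img: np.ndarray, sigma: float) -> np.ndarray:
    """Dense 2-D convolution with the truncated normalized Gaussian."""
    radius = math.ceil(3.0 * sigma)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    padded = np.pad(img.astype(np.float64), radius, mode="symmetric")
    out = np.empty(img.shape, dtype=np.float64)
    w = 2 * radius + 1
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = float((padded[i : i + w, j : j + w] * kernel).sum())
    return out


_SX = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_SY = _SX.T


def sobel_oracle(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Explicit 3x3 Sobel stencil; returns (magnitude, direction)."""
    padded = np.pad(img.astype(np.float64), 1, mode="symmetric")
    mag = np.empty(img.shape, dtype=np.float64)
    direction = np.empty(img.shape, dtype=np.float64)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            patch = padded[i : i + 3, j : j + 3]
            gx = float((patch * _SX).sum())
            gy = float((patch * _SY).sum())
            mag[i, j] = math.hypot(gx, gy)
            d = math.atan2(gy, gx)
            direction[i, j] = math.pi if d == -math.pi else d
    return mag, direction


def nms_oracle(mag: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Per-pixel non-maximum suppression with the 4-sector table.

    Sector boundaries at odd multiples of 22.5 degrees; out-of-grid
    neighbours are ignored; ties kept (>= comparison).
    """
    rows, cols = mag.shape
    out = np.zeros_like(mag, dtype=np.float64)
    for i in range(rows):
        for j in range(cols):
            deg = math.degrees(direction[i, j] % math.pi)
            if deg < 22.5 or deg >= 157.5:
                dr, dc = 0, 1
            elif deg < 67.5:
                dr, dc = 1, 1
            elif deg < 112.5:
                dr, dc = 1, 0
            else:
                dr, dc = 1, -1
            keep = True
            for s in (1, -1):
                ni, nj = i + s * dr, j + s * dc
                if 0 <= ni < rows and 0 <= nj < cols and mag[i, j] < mag[ni, nj]:
                    keep = False
                    break
            if keep:
                out[i, j] = mag[i, j]
    return out


def hysteresis_oracle(thinned: np.ndarray, low: float, high: float) -> np.ndarray:
    """Breadth-first flood from strong pixels through weak 8-neighbours."""
    rows, cols = thinned.shape
    out = np.zeros(thinned.shape, dtype=bool)
    queue = deque(
        (i, j) for i in range(rows) for j in range(cols) if thinned[i, j] >= high
    )
    for i, j in queue:
        out[i, j] = True
    while queue:
        i, j = queue.popleft()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ni, nj = i + di, j + dj
                if (
                    0 <= ni < rows
                    and 0 <= nj < cols
                    and not out[ni, nj]
                    and thinned[ni, nj] >= low
                ):
                    out[ni, nj] = True
                    queue.append((ni, nj))
    return out


def count_components_oracle(mask: np.ndarray, connectivity: int = 8) -> int:
    """Flood-fill component counting (BFS)."""
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    mask = np.asarray(mask, dtype=bool)
    rows, cols = mask.shape
    seen = np.zeros(mask.shape, dtype=bool)
    count = 0
    for si, sj in zip(*np.nonzero(mask)):
        if seen[si, sj]:
            continue
        count += 1
        queue = deque([(si, sj)])
        seen[si, sj] = True
        while queue:
            i, j = queue.popleft()
            for di, dj in nbrs:
                ni, nj = i + di, j + dj
                if 0 <= ni < rows and 0 <= nj < cols and mask[ni, nj] and not seen[ni, nj]:
                    seen[ni, nj] = True
                    queue.append((ni, nj))
    return count


def quantile_type4_oracle(values: np.ndarray, q: float) -> float:
    """Sort-based linear interpolation between order statistics at h = q*n."""
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = x.size
    h = q * n
    if h <= 1:
        return float(x[0])
    if h >= n:
        return float(x[-1])
    j = int(math.floor(h))
    g = h - j
    if g == 0:
        return float(x[j - 1])
    return float(x[j - 1] + g * (x[j] - x[j - 1]))


def studentized_range_sf_oracle(q: float, k: int, df: float) -> float:
    """P(Q > q) for the studentized range, by direct numerical quadrature.

    Outer integral over the scale (chi distribution with df degrees of
    freedom, normalized by sqrt(df)); inner integral over the location of
    the range with normal-CDF powers.  Fixed high-order Gauss-Legendre
    grids on both axes (the integrand is smooth); absolute accuracy is far
    below the 1e-4 comparison tolerance.
    """
    # inner grid over the location z
    zn, zw = np.polynomial.legendre.leggauss(240)
    z = -8.0 + (zn + 1.0) * 8.0  # map [-1,1] -> [-8, 8]
    zw = zw * 8.0
    # outer grid over u = s * sqrt(df), which follows chi(df)
    un, uw = np.polynomial.legendre.leggauss(240)
    u_hi = math.sqrt(df) * 10.0
    u = (un + 1.0) * (u_hi / 2.0)
    uw = uw * (u_hi / 2.0)

    s = u / math.sqrt(df)  # scale for each outer node
    # inner integral for every outer node at once: shape (n_u, n_z)
    phi = norm.pdf(z)[None, :]
    inner_vals = (
        phi * (norm.cdf(z)[None, :] - norm.cdf(z[None, :] - q * s[:, None])) ** (k - 1)
    ) @ zw
    cdf = float((chi.pdf(u, df) * k * inner_vals) @ uw)
    return min(max(1.0 - cdf, 0.0), 1.0)
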