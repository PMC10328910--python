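"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as the most literal possible enumeration, kept
deliberately separate from the package's own (vectorized) code paths.
"""

from __future__ import annotations

import numpy as np

DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))


def bruteforce_masked_glcm(quantized, mask, distance, n_levels, symmetric=True):
    """Double loop over all pixel pairs at the four principal offsets."""
    H, W = quantized.shape
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    for r in range(H):
        for c in range(W):
            if not mask[r, c]:
                continue
            for dr, dc in DIRECTIONS:
                r2, c2 = r + dr * distance, c + dc * distance
                if 0 <= r2 < H and 0 <= c2 < W and mask[r2, c2]:
                    counts[quantized[r, c], quantized[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts


def bruteforce_knn_edges(points, k):
    """All-pairs distances, ties broken by index, symmetrized edge set."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    k = min(k, n - 1)
    edges = set()
    for i in range(n):
        dists = sorted(
            (float(np.hypot(*(points[i] - points[j]))), j)
            for j in range(n)
            if j != i
        )
        for _, j in dists[:k]:
            edges.add((min(i, j), max(i, j)))
    return sorted(edges)


def bruteforce_cflcm(levels, edges, n_levels):
    """Pair enumeration over edges; symmetric, normalized."""
    M = np.zeros((n_levels, n_levels))
    for i, j in edges:
        M[levels[i] - 1, levels[j] - 1] += 1
        M[levels[j] - 1, levels[i] - 1] += 1
    total = M.sum()
    return M / total if total > 0 else M


def bruteforce_disk_pixels(center, radius, shape):
    """Pixels whose center lies within `radius` of `center`."""
    out = []
    for r in range(shape[0]):
        for c in range(shape[1]):
            if (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius**2:
                out.append((r, c))
    return out


def straightline_roi_vector(features, centroids, n_levels=8, k=5):
    """Plain-loop reimplementation of the 12-statistic ROI aggregation.

    Uses its own quantile binning, its own knn edges and scalar-loop
    co-occurrence statistics; shares no code with the package.
    """
    X = np.asarray(features, dtype=float)
    n, F = X.shape
    edges = bruteforce_knn_edges(centroids, k)
    out = []
    for f in range(F):
        vals = X[:, f]
        mean = vals.sum() / n
        sd = np.sqrt(((vals - mean) ** 2).sum() / (n - 1))
        # quantile levels
        qs = np.quantile(vals, np.linspace(0, 1, n_levels + 1))
        if qs[0] == qs[-1]:
            levels = np.ones(n, dtype=int)
        else:
            levels = np.array(
                [1 + int(np.searchsorted(qs[1:-1], v, side="left")) for v in vals]
            )
        P = bruteforce_cflcm(levels, edges, n_levels)
        out.extend([mean, sd] + list(_scalar_cooc_stats(P)))
    return np.array(out)


def _scalar_cooc_stats(P):
    L = P.shape[0]
    total = P.sum()
    if total == 0:
        return [0.0] * 10
    contrast = dissim = homog = asm = entropy = idm = 0.0
    mu_x = mu_y = 0.0
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    for i in range(L):
        mu_x += i * px[i]
        mu_y += i * py[i]
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(L))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(L))
    cross = 0.0
    shade = prom = 0.0
    maxp = 0.0
    for i in range(L):
        for j in range(L):
            p = P[i, j]
            contrast += (i - j) ** 2 * p
            dissim += abs(i - j) * p
            homog += p / (1 + abs(i - j))
            asm += p * p
            if p > 0:
                entropy -= p * np.log(p)
            cross += i * j * p
            shade += (i + j - mu_x - mu_y) ** 3 * p
            prom += (i + j - mu_x - mu_y) ** 4 * p
            maxp = max(maxp, p)
            idm += p / (1 + (i - j) ** 2)
    corr = (
        (cross - mu_x * mu_y) / np.sqrt(var_x * var_y)
        if var_x > 0 and var_y > 0
        else 0.0
    )
    return [contrast, dissim, homog, asm, entropy, corr, shade, prom, maxp, idm]
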