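"""Independent brute-force oracles used only by the tests.

These deliberately re-derive quantities by enumeration or elementary
formulas, staying independent of the library code paths they check.
"""

import itertools
import math

import numpy as np


def brute_force_quantize(points: np.ndarray, weights: np.ndarray, k: int) -> float:
    """Exhaustive minimum within-cluster weighted SSE over all K-partitions.

    Enumerates every assignment of points to clusters (the first point is
    pinned to cluster 0, which only removes label permutations) and
    evaluates SSE = sum_i w_i |x_i|^2 - sum_c |s_c|^2 / W_c in vectorized
    chunks.
    """
    points = np.asarray(points, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n = len(points)
    if n == 1 or k >= n:
        return 0.0
    total = float((weights[:, None] * points**2).sum())
    m = n - 1  # free points (point 0 pinned to cluster 0)
    n_assign = k**m
    codes = np.arange(n_assign)
    best = math.inf
    powers = k ** np.arange(m)
    for start in range(0, n_assign, 100_000):
        chunk = codes[start : start + 100_000]
        digits = (chunk[:, None] // powers[None, :]) % k  # (A, m)
        assign = np.concatenate(
            [np.zeros((len(chunk), 1), dtype=int), digits], axis=1
        )  # (A, n)
        onehot = assign[:, :, None] == np.arange(k)[None, None, :]  # (A, n, k)
        wc = np.einsum("ank,n->ak", onehot, weights)
        sc = np.einsum("ank,nd->akd", onehot, weights[:, None] * points)
        with np.errstate(divide="ignore", invalid="ignore"):
            explained = np.where(wc > 0, (sc**2).sum(axis=2) / wc, 0.0)
        sse = total - explained.sum(axis=1)
        best = min(best, float(sse.min()))
    return best


def sort_based_midrank(values) -> np.ndarray:
    """Midranks via explicit sorting and tie-group averaging."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and values[order[j]] == values[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2.0  # mean of positions i+1 .. j
        for t in range(i, j):
            ranks[order[t]] = avg
        i = j
    return np.asarray(ranks)


def friedman_statistic_from_scratch(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square, written out long-hand."""
    n, k = ranks.shape
    col = ranks.sum(axis=0)
    num = (k - 1) * sum((r - n * (k + 1) / 2.0) ** 2 for r in col)
    den = float((ranks**2).sum()) - n * k * (k + 1) ** 2 / 4.0
    return 0.0 if den <= 0 else num / den


def friedman_exact_p_enumeration(values: np.ndarray) -> float:
    """Exact permutation p by literally enumerating all (k!)^n orderings."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    ranks = np.vstack([sort_based_midrank(row) for row in values])
    observed = friedman_statistic_from_scratch(ranks)
    perms = list(itertools.permutations(range(k)))
    count = total = 0
    for combo in itertools.product(perms, repeat=n):
        permuted = np.vstack([ranks[i][list(p)] for i, p in enumerate(combo)])
        total += 1
        if friedman_statistic_from_scratch(permuted) >= observed - 1e-9:
            count += 1
    return count / total


def rasterize_tube_bruteforce(shape, points: np.ndarray, radius: float) -> np.ndarray:
    """Voxel-by-voxel tube rasterization (slow, loop-based)."""
    out = np.zeros(shape, dtype=bool)
    lo = np.maximum(np.floor(points.min(axis=0) - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(points.max(axis=0) + radius + 2).astype(int), shape)
    r2 = radius**2
    for i in range(lo[0], hi[0]):
        for j in range(lo[1], hi[1]):
            for kk in range(lo[2], hi[2]):
                v = np.array([i, j, kk], dtype=float)
                d2 = ((points - v) ** 2).sum(axis=1).min()
                if d2 <= r2:
                    out[i, j, kk] = True
    return out
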