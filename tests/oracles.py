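"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results from first principles (recursive
definitions, triple loops, naive formulas) instead of sharing code with
the package, so agreement is evidence of correctness rather than
tautology.
"""

from __future__ import annotations

import numpy as np


def brute_wpgma(dist: np.ndarray):
    """WPGMA by its recursive definition on nested-tuple clusters.

    Cluster distance is defined recursively: d((A1, A2), C) =
    (d(A1, C) + d(A2, C)) / 2, grounded in the input matrix for leaves.
    Ties are broken by the lexicographically smallest sorted pair of
    minimal leaf indices.  Returns (heights, partitions) where
    ``partitions[k]`` is the list of leaf-index frozensets present after
    the first k merges.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    cache: dict[tuple, float] = {}

    def d(a, b) -> float:
        key = (a, b)
        if key in cache:
            return cache[key]
        if isinstance(a, int) and isinstance(b, int):
            val = dist[a, b]
        elif isinstance(a, tuple):
            val = (d(a[0], b) + d(a[1], b)) / 2.0
        else:
            val = (d(a, b[0]) + d(a, b[1])) / 2.0
        cache[key] = val
        return val

    def leaves(c) -> frozenset:
        if isinstance(c, int):
            return frozenset([c])
        return leaves(c[0]) | leaves(c[1])

    clusters: list = list(range(n))
    heights = []
    partitions = [[leaves(c) for c in clusters]]
    for _ in range(n - 1):
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = d(clusters[i], clusters[j])
                key = (
                    h,
                    tuple(sorted((min(leaves(clusters[i])),
                                  min(leaves(clusters[j]))))),
                )
                if best is None or key < best[0]:
                    best = (key, i, j)
        (h, _), i, j = best
        merged = (clusters[i], clusters[j])
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        heights.append(h)
        partitions.append([leaves(c) for c in clusters])
    return np.array(heights), partitions


def floyd_warshall_closeness(weights: np.ndarray) -> np.ndarray:
    """Closeness centrality 1/farness via triple-loop Floyd-Warshall."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    sp = w.copy()
    np.fill_diagonal(sp, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if sp[i, k] + sp[k, j] < sp[i, j]:
                    sp[i, j] = sp[i, k] + sp[k, j]
    return 1.0 / sp.sum(axis=1)


def naive_dcc(frames: np.ndarray) -> np.ndarray:
    """Cross-correlation by the direct per-pair formula (no streaming)."""
    frames = np.asarray(frames, dtype=float)
    f, n, _ = frames.shape
    d = frames - frames.mean(axis=0)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            num = np.mean(np.sum(d[:, i, :] * d[:, j, :], axis=1))
            den = np.sqrt(
                np.mean(np.sum(d[:, i, :] ** 2, axis=1))
                * np.mean(np.sum(d[:, j, :] ** 2, axis=1))
            )
            out[i, j] = num / den
    np.fill_diagonal(out, 1.0)
    return out


def random_connected_walk(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random 3D walk with 3.0-4.5 A steps: connected at r_c = 7.5 A."""
    steps = rng.normal(size=(n - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    steps *= rng.uniform(3.0, 4.5, size=(n - 1, 1))
    return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
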