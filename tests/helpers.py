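"""Independent oracles used by the test suite (kept free of rpfam internals)."""

import numpy as np


def brute_force_complete_linkage(dist: np.ndarray) -> list[float]:
    """Exhaustive complete-linkage agglomeration over an explicit cluster list.

    Returns the sorted merge heights.  At every step the pair of clusters
    with the smallest maximum pairwise member distance is merged.
    """
    n = dist.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights: list[float] = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return sorted(heights)


def pairwise_euclidean(rows: np.ndarray) -> np.ndarray:
    """Double-loop Euclidean distance oracle."""
    n = rows.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sqrt(((rows[i] - rows[j]) ** 2).sum())
    return out
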