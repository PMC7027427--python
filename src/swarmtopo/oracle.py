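"""Brute-force Vietoris-Rips Betti numbers for small point clouds.

Builds the full complex (vertices, edges, triangles) present at a given
scale and computes b0 and b1 from exact GF(2) boundary-matrix ranks:

    b0 = V - rank d1,     b1 = (E - rank d1) - rank d2.

Exponential in cloud size; intended as an independent correctness oracle for
the incremental persistence engine on clouds of at most ~10 points.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.spatial.distance import squareform, pdist


def gf2_rank(rows: list[int]) -> int:
    """Rank over GF(2) of a matrix whose rows are given as Python bitmasks."""
    rank = 0
    pivots: list[int] = []
    for row in rows:
        for p in pivots:
            row = min(row, row ^ p)
        if row:
            pivots.append(row)
            pivots.sort(reverse=True)
            rank += 1
    return rank


def betti_numbers(points: np.ndarray, eps: float) -> tuple[int, int]:
    """(b0, b1) of the VR complex at scale eps (edges at distance <= eps)."""
    x = np.asarray(points, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("empty point cloud")
    if n == 1:
        return 1, 0
    dist = squareform(pdist(x))

    edges = [(i, j) for i, j in combinations(range(n), 2) if dist[i, j] <= eps]
    edge_index = {e: q for q, e in enumerate(edges)}
    triangles = [
        (i, j, k)
        for i, j, k in combinations(range(n), 3)
        if max(dist[i, j], dist[i, k], dist[j, k]) <= eps
    ]

    d1 = [(1 << i) | (1 << j) for i, j in edges]  # columns of d1 as vertex masks
    d2 = [
        (1 << edge_index[(i, j)])
        | (1 << edge_index[(i, k)])
        | (1 << edge_index[(j, k)])
        for i, j, k in triangles
    ]
    r1 = gf2_rank(d1)
    r2 = gf2_rank(d2)
    b0 = n - r1
    b1 = len(edges) - r1 - r2
    return b0, b1


def betti_curves(points: np.ndarray, eps_values: np.ndarray) -> np.ndarray:
    """Stacked (2, len(eps_values)) array of b0 and b1 across scales."""
    out = np.empty((2, len(eps_values)), dtype=np.int64)
    for q, eps in enumerate(eps_values):
        out[0, q], out[1, q] = betti_numbers(points, eps)
    return out
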