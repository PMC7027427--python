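"""Compiled kernels for Vietoris-Rips persistence in dimensions 0 and 1.

H0 comes from a union-find pass over the distance-sorted edge list (the merge
heights are the single-linkage dendrogram heights). H1 comes from incremental
GF(2) column reduction of the triangle boundary matrix: a triangle column is
reduced against the stored column sharing its pivot (largest edge, in the
edge filtration order) until it either finds a free pivot — contributing one
unit of rank and one (edge birth, triangle death) pair — or vanishes.

Because the rank of a set of columns does not depend on the order in which
they are reduced, Betti curves evaluated on a fixed scale grid only require
triangles grouped by grid bin, not fully sorted; the crocker path exploits
this with a counting sort.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _union_find_h0(edge_i, edge_j, edge_len, n_points):
    """Process distance-sorted edges; return (deaths, n_deaths, edge_negative).

    deaths[:n_deaths] are the component merge heights in ascending order.
    edge_negative[e] is True when sorted edge e merged two components (and is
    therefore unavailable as an H1 creator).
    """
    parent = np.arange(n_points)
    deaths = np.empty(n_points - 1 if n_points > 1 else 0, np.float64)
    negative = np.zeros(edge_i.shape[0], np.bool_)
    nd = 0
    for e in range(edge_i.shape[0]):
        a = edge_i[e]
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        b = edge_j[e]
        while parent[b] != b:
            parent[b] = parent[parent[b]]
            b = parent[b]
        if a != b:
            if a < b:
                parent[b] = a
            else:
                parent[a] = b
            deaths[nd] = edge_len[e]
            nd += 1
            negative[e] = True
    return deaths, nd, negative


@njit(cache=True)
def _enumerate_triangles(dist, rank, thresh):
    """All triangles with diameter <= thresh.

    dist is the square distance matrix; rank maps a condensed pair index to
    the edge's position in the distance-sorted edge order. Returns
    (tri_edges [T x 3] edge ranks sorted ascending per row, tri_diam [T]).
    """
    n = dist.shape[0]
    max_t = n * (n - 1) * (n - 2) // 6
    tri_edges = np.empty((max_t, 3), np.int64)
    tri_diam = np.empty(max_t, np.float64)
    cnt = 0
    for i in range(n):
        base_i = n * i - i * (i + 1) // 2 - i - 1
        for j in range(i + 1, n):
            dij = dist[i, j]
            if dij > thresh:
                continue
            base_j = n * j - j * (j + 1) // 2 - j - 1
            e_ij = rank[base_i + j]
            for k in range(j + 1, n):
                dik = dist[i, k]
                if dik > thresh:
                    continue
                djk = dist[j, k]
                if djk > thresh:
                    continue
                dm = dij
                if dik > dm:
                    dm = dik
                if djk > dm:
                    dm = djk
                a = e_ij
                b = rank[base_i + k]
                c = rank[base_j + k]
                # sort three edge ranks ascending
                if a > b:
                    a, b = b, a
                if b > c:
                    b, c = c, b
                if a > b:
                    a, b = b, a
                tri_edges[cnt, 0] = a
                tri_edges[cnt, 1] = b
                tri_edges[cnt, 2] = c
                tri_diam[cnt] = dm
                cnt += 1
    return tri_edges[:cnt], tri_diam[:cnt]


@njit(cache=True)
def _reduce_d2(order, tri_edges, n_edges):
    """Incremental GF(2) reduction of triangle boundary columns.

    ``order`` gives the processing sequence (must be non-decreasing in
    filtration value for the cumulative ranks/pairs to be meaningful).
    Returns pivot_of[t] = pivot edge rank of triangle t's reduced column, or
    -1 when the column reduced to zero.
    """
    n_t = order.shape[0]
    pivot_of = np.full(n_t, -1, np.int64)
    col_start = np.full(n_edges, -1, np.int64)
    col_len = np.zeros(n_edges, np.int64)
    pool = np.empty(max(64, 4 * n_t), np.int64)
    used = 0
    cur = np.empty(256, np.int64)
    tmp = np.empty(256, np.int64)

    for oi in range(n_t):
        t = order[oi]
        cur[0] = tri_edges[t, 0]
        cur[1] = tri_edges[t, 1]
        cur[2] = tri_edges[t, 2]
        m = 3
        while m > 0:
            p = cur[m - 1]
            s = col_start[p]
            if s == -1:
                if used + m > pool.shape[0]:
                    newpool = np.empty(max(2 * pool.shape[0], used + m), np.int64)
                    newpool[:used] = pool[:used]
                    pool = newpool
                col_start[p] = used
                col_len[p] = m
                pool[used:used + m] = cur[:m]
                used += m
                pivot_of[t] = p
                break
            ln = col_len[p]
            need = m + ln
            if tmp.shape[0] < need:
                tmp = np.empty(2 * need, np.int64)
            a = 0
            b = 0
            k = 0
            while a < m and b < ln:
                x = cur[a]
                y = pool[s + b]
                if x == y:
                    a += 1
                    b += 1
                elif x < y:
                    tmp[k] = x
                    k += 1
                    a += 1
                else:
                    tmp[k] = y
                    k += 1
                    b += 1
            while a < m:
                tmp[k] = cur[a]
                k += 1
                a += 1
            while b < ln:
                tmp[k] = pool[s + b]
                k += 1
                b += 1
            if cur.shape[0] < k:
                cur = np.empty(2 * k, np.int64)
            cur[:k] = tmp[:k]
            m = k
    return pivot_of
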