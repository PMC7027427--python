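"""Topological summaries of time-varying point clouds: crocker matrices.

For each sampled frame of a simulation the agent positions (optionally
augmented with time-delayed position, or with velocity) form a point cloud.
Vietoris-Rips persistent homology of that cloud — with the ball-diameter
convention, an edge appears at a scale equal to the pairwise distance —
yields Betti curves b0(eps) and b1(eps) on a fixed logarithmic grid of 200
scales. Stacking the curves of successive frames column by column produces
the crocker matrix b_k(eps_q, t_j), a vectorizable topological signature of
the whole simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from ._cohom import _h1_cohomology
from ._reduction import _enumerate_triangles, _reduce_d2, _union_find_h0

__all__ = [
    "EpsilonGrid",
    "PersistenceDiagram",
    "Crocker",
    "epsilon_grid",
    "rips_persistence",
    "betti_curve",
    "betti_curves_grid",
    "normalize_library",
    "position_clouds",
    "time_delay_embed",
    "position_velocity_embed",
    "crocker",
    "compute_crockers",
    "vectorize",
]

#: Default frame stride (in raw 0.05-spaced frames) for every cloud sequence.
DEFAULT_STRIDE = 23

#: Default time-delay lag, in raw frames (5 * 0.05 = 0.25 time units).
DEFAULT_DELAY = 5


@dataclass(frozen=True)
class EpsilonGrid:
    """Logarithmic scale grid eps_q = 10^(-4 + q * delta), q = 1..n."""

    values: np.ndarray
    delta: float

    @classmethod
    def default(cls) -> "EpsilonGrid":
        # 200 points spanning 10^-3.98 .. 10^0.
        delta = 4.0 / 200.0
        q = np.arange(1, 201)
        return cls(values=10.0 ** (-4.0 + q * delta), delta=delta)

    def __len__(self) -> int:
        return len(self.values)


def epsilon_grid() -> EpsilonGrid:
    """The standard 200-point logarithmic scale grid on (10^-4, 1]."""
    return EpsilonGrid.default()


@dataclass
class PersistenceDiagram:
    """Birth/death pairs per homology dimension; death = inf for essential
    classes (those alive at the filtration threshold)."""

    dgms: list  # dgms[k]: (m_k, 2) float array
    threshold: float

    def betti_at(self, eps: float, k: int) -> int:
        d = self.dgms[k]
        if len(d) == 0:
            return 0
        return int(np.count_nonzero((d[:, 0] <= eps) & (eps < d[:, 1])))


@dataclass
class Crocker:
    """Betti numbers b_k on the (scale grid) x (sampled frames) lattice.

    betti[q, j] is b_k of the cloud at frame_indices[j] evaluated at
    grid.values[q]; rows are ordered by increasing scale.
    """

    betti: np.ndarray  # (len(grid), n_frames) nonnegative int
    k: int
    frame_indices: np.ndarray
    grid: EpsilonGrid
    embedding: str

    def __post_init__(self):
        if self.betti.shape != (len(self.grid), len(self.frame_indices)):
            raise ValueError("betti matrix shape must be (scales, frames)")


def _sorted_edges(points: np.ndarray):
    """Distance-sorted edge list with lexicographic tie-breaks.

    Returns (edge_i, edge_j, edge_len, rank) where rank maps a condensed
    pair index to the edge's filtration position.
    """
    n = len(points)
    d = pdist(points)
    ii, jj = np.triu_indices(n, 1)
    order = np.lexsort((jj, ii, d))
    rank = np.empty(len(d), dtype=np.int64)
    rank[order] = np.arange(len(d), dtype=np.int64)
    return ii[order].astype(np.int64), jj[order].astype(np.int64), d[order], rank


def _square(points: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import squareform

    return squareform(pdist(points))


def _enclosing_radius(dist: np.ndarray) -> float:
    """min over points of the max distance to any other point.

    At scales >= this radius the VR complex is a cone (hence contractible),
    so every H1 class has died; the H1 filtration can be truncated there.
    """
    return float(dist.max(axis=0).min())


def rips_persistence(points: np.ndarray, max_dim: int = 1,
                     threshold: float = np.inf) -> PersistenceDiagram:
    """VR persistence diagram of a point cloud, dimensions 0..max_dim (<= 1).

    H0 classes are born at 0; one essential class always remains. H1 pairs
    with zero persistence (birth == death) are discarded. With equal
    filtration values the individual pairings depend on tie order, but Betti
    counts at any scale do not.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    if x.size == 0:
        raise ValueError("empty point cloud")
    if not np.all(np.isfinite(x)):
        raise ValueError("point cloud must be finite")
    if max_dim > 1:
        raise NotImplementedError("homology computed only up to dimension 1")
    n = len(x)
    if n == 1:
        dgms = [np.array([[0.0, np.inf]])] + [np.empty((0, 2))] * max_dim
        return PersistenceDiagram(dgms=dgms, threshold=threshold)

    edge_i, edge_j, edge_len, rank = _sorted_edges(x)
    deaths, nd, negative = _union_find_h0(edge_i, edge_j, edge_len, n)
    h0_deaths = deaths[:nd].copy()
    h0_deaths[h0_deaths > threshold] = np.inf
    h0 = np.column_stack([np.zeros(nd + 1), np.append(h0_deaths, np.inf)])
    dgms = [h0]

    if max_dim >= 1:
        dist = _square(x)
        t_eff = min(threshold, _enclosing_radius(dist))
        births, deaths, essential = _h1_cohomology(
            dist, edge_i, edge_j, edge_len, negative, t_eff)
        keep = births < deaths
        finite = np.column_stack([births[keep], deaths[keep]])
        if len(essential):
            ess = np.column_stack([essential, np.full(len(essential), np.inf)])
            h1 = np.vstack([finite, ess])
        else:
            h1 = finite
        dgms.append(h1)
    return PersistenceDiagram(dgms=dgms, threshold=threshold)


def betti_curve(diagram: PersistenceDiagram, grid: EpsilonGrid,
                k: int) -> np.ndarray:
    """b_k on the scale grid: counts pairs with birth <= eps < death."""
    d = diagram.dgms[k]
    eps = grid.values
    if len(d) == 0:
        return np.zeros(len(eps), dtype=np.int64)
    births = np.sort(d[:, 0])
    deaths = np.sort(d[:, 1])
    born = np.searchsorted(births, eps, side="right")
    dead = np.searchsorted(deaths, eps, side="right")
    return (born - dead).astype(np.int64)


def betti_curves_grid(points: np.ndarray, grid: EpsilonGrid,
                      max_dim: int = 1) -> np.ndarray:
    """(max_dim+1, len(grid)) Betti curves evaluated on the scale grid.

    b0 comes from the single-linkage merge heights; b1 from the cohomology
    persistence pairs truncated at min(grid max, enclosing radius) — beyond
    the enclosing radius the complex is a cone and b1 is identically zero.
    Agrees with betti_curve(rips_persistence(...)) everywhere.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(x)
    eps = grid.values
    out = np.zeros((max_dim + 1, len(eps)), dtype=np.int64)
    if n == 1:
        out[0, :] = 1
        return out

    edge_i, edge_j, edge_len, rank = _sorted_edges(x)
    deaths, nd, negative = _union_find_h0(edge_i, edge_j, edge_len, n)
    out[0] = n - np.searchsorted(deaths[:nd], eps, side="right")

    if max_dim >= 1:
        dist = _square(x)
        t_eff = min(eps[-1], _enclosing_radius(dist))
        births, fdeaths, essential = _h1_cohomology(
            dist, edge_i, edge_j, edge_len, negative, t_eff)
        all_births = np.sort(np.concatenate([births, essential]))
        all_deaths = np.sort(fdeaths)
        out[1] = (np.searchsorted(all_births, eps, side="right")
                  - np.searchsorted(all_deaths, eps, side="right"))
    return out


def _betti_curves_via_boundary_reduction(points: np.ndarray,
                                         grid: EpsilonGrid) -> np.ndarray:
    """Independent mid-scale H1 route: incremental GF(2) rank of the triangle
    boundary matrix, b1 = dim Z1 - rank d2 per grid scale.

    Slower than the cohomology engine but entirely separate machinery; used
    to cross-validate it on clouds too large for the brute-force oracle.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(x)
    eps = grid.values
    out = np.zeros((2, len(eps)), dtype=np.int64)
    edge_i, edge_j, edge_len, rank = _sorted_edges(x)
    deaths, nd, negative = _union_find_h0(edge_i, edge_j, edge_len, n)
    out[0] = n - np.searchsorted(deaths[:nd], eps, side="right")

    dist = _square(x)
    t_eff = min(eps[-1], _enclosing_radius(dist))
    tri_edges, tri_diam = _enumerate_triangles(dist, rank, t_eff)
    # grid evaluation only needs ranks of column *sets*, which are
    # order-independent, so bucketing triangles by grid bin suffices
    bins = np.searchsorted(eps, tri_diam, side="left")
    order = np.argsort(bins, kind="stable").astype(np.int64)
    pivot_of = _reduce_d2(order, tri_edges, len(edge_len))

    n_edges_at = np.searchsorted(edge_len, eps, side="right")
    rank_at = np.cumsum(np.bincount(bins[pivot_of >= 0],
                                    minlength=len(eps)))[:len(eps)]
    b1 = n_edges_at - n + out[0] - rank_at
    b1[eps > t_eff] = 0
    out[1] = b1
    return out


def normalize_library(position_arrays):
    """Global scaling of (already capped) position data to [-1, 1]^2.

    The constant is the maximum sup-norm over every agent, frame and
    simulation supplied; every array is divided by it. Returns
    (scaled_arrays, constant). When escape runs capped at 10 are present the
    constant is 10 by construction.
    """
    arrays = list(position_arrays)
    if not arrays:
        raise ValueError("empty library")
    constant = max(float(np.abs(a).max()) for a in arrays)
    if constant == 0.0:
        constant = 1.0  # degenerate all-at-origin library; documented rule
    return [a / constant for a in arrays], constant


def _sample_indices(n_frames: int, stride: int) -> np.ndarray:
    # frames stride, 2*stride, ..., in one-based counting; 0-based: stride-1, ...
    return np.arange(stride - 1, n_frames, stride)


def position_clouds(positions: np.ndarray, stride: int = DEFAULT_STRIDE):
    """2D clouds at the downsampled frames (87 for the standard protocol).

    positions: (N, M, 2) array (typically capped and library-normalized).
    Returns (clouds (F, N, 2), frame_indices).
    """
    idx = _sample_indices(positions.shape[1], stride)
    return positions[:, idx, :].transpose(1, 0, 2), idx


def time_delay_embed(positions: np.ndarray, delay_frames: int = DEFAULT_DELAY,
                     stride: int = DEFAULT_STRIDE):
    """4D clouds [x_i(t_j), x_i(t_j - delay)] on the delayed frame grid.

    The first downsampled frame is dropped, leaving 86 clouds for the
    standard protocol; the lag must not reach before t = 0.
    Returns (clouds (F, N, 4), frame_indices).
    """
    idx = _sample_indices(positions.shape[1], stride)[1:]
    if len(idx) == 0 or idx[0] - delay_frames < 0:
        raise ValueError("time-delay lag reaches before the first frame")
    now = positions[:, idx, :]
    lagged = positions[:, idx - delay_frames, :]
    return np.concatenate([now, lagged], axis=2).transpose(1, 0, 2), idx


def position_velocity_embed(positions: np.ndarray, velocities: np.ndarray,
                            pos_constant: float, vel_constant: float,
                            stride: int = DEFAULT_STRIDE):
    """4D clouds [x-hat_i(t), v-hat_i(t)] with independent normalizations.

    Positions are scaled by the library-wide max sup-norm, velocities by the
    library-wide max speed (both passed in); a zero velocity constant falls
    back to 1. Provided for the comparison showing why a naive
    position+velocity embedding misses the double-ring structure.
    """
    if vel_constant == 0.0:
        vel_constant = 1.0
    idx = _sample_indices(positions.shape[1], stride)
    x = positions[:, idx, :] / pos_constant
    v = velocities[:, idx, :] / vel_constant
    return np.concatenate([x, v], axis=2).transpose(1, 0, 2), idx


def crocker(clouds: np.ndarray, grid: EpsilonGrid, k: int,
            frame_indices: np.ndarray | None = None,
            embedding: str = "position_2d") -> Crocker:
    """Crocker matrix of one homology dimension for a cloud sequence."""
    return compute_crockers(clouds, grid, max_dim=k,
                            frame_indices=frame_indices,
                            embedding=embedding)[k]


def compute_crockers(clouds: np.ndarray, grid: EpsilonGrid, max_dim: int = 1,
                     frame_indices: np.ndarray | None = None,
                     embedding: str = "position_2d") -> dict:
    """b0 (and b1) crockers of a sequence of point clouds in one pass.

    clouds: (F, N, d) array or sequence of (N, d) arrays.
    Returns {k: Crocker}.
    """
    n_frames = len(clouds)
    if n_frames == 0:
        raise ValueError("empty cloud sequence")
    if frame_indices is None:
        frame_indices = np.arange(n_frames)
    betti = np.zeros((max_dim + 1, len(grid), n_frames), dtype=np.int64)
    for j in range(n_frames):
        try:
            betti[:, :, j] = betti_curves_grid(clouds[j], grid, max_dim=max_dim)
        except Exception as exc:  # noqa: BLE001 - annotate frame and re-raise
            raise RuntimeError(f"persistence failed at frame {j} "
                               f"(raw index {frame_indices[j]})") from exc
    return {
        k: Crocker(betti=betti[k], k=k, frame_indices=np.asarray(frame_indices),
                   grid=grid, embedding=embedding)
        for k in range(max_dim + 1)
    }


def plateau_value(betti_column: np.ndarray) -> int:
    """Value of the longest contiguous constant nonzero run in a Betti curve.

    Used to read off the dominant topological signature of a crocker column
    (e.g. the loop count of a ring-like configuration, which is constant
    over a wide band of scales).
    """
    best_v, best_len = 0, 0
    run_v, run_len = int(betti_column[0]), 1
    for x in betti_column[1:]:
        x = int(x)
        if x == run_v:
            run_len += 1
        else:
            if run_v > 0 and run_len > best_len:
                best_v, best_len = run_v, run_len
            run_v, run_len = x, 1
    if run_v > 0 and run_len > best_len:
        best_v, best_len = run_v, run_len
    return best_v


def vectorize(*crockers: Crocker) -> np.ndarray:
    """Row-major flattening of one or more crockers (b0 before b1).

    Frame grids must match when concatenating.
    """
    if not crockers:
        raise ValueError("nothing to vectorize")
    shape = crockers[0].betti.shape
    for c in crockers[1:]:
        if c.betti.shape != shape or not np.array_equal(
                c.frame_indices, crockers[0].frame_indices):
            raise ValueError("crockers must share the same (scale, frame) grid")
    ordered = sorted(crockers, key=lambda c: c.k)
    return np.concatenate([c.betti.ravel() for c in ordered]).astype(float)
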