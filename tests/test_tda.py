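"""Topological machinery: scale grid, persistence, embeddings, crockers.

The incremental persistence engine is checked three ways: against the exact
brute-force boundary-matrix oracle on small random clouds (all grid scales),
against an independent GF(2) rank route on mid-size clouds, and against
closed-form expectations on structured configurations.
"""

import numpy as np
import pytest

from swarmtopo import (
    epsilon_grid,
    EpsilonGrid,
    betti_curve,
    betti_curves_grid,
    compute_crockers,
    normalize_library,
    position_clouds,
    position_velocity_embed,
    rips_persistence,
    time_delay_embed,
    vectorize,
)
from swarmtopo.oracle import betti_curves as oracle_curves
from swarmtopo.tda import _betti_curves_via_boundary_reduction


class TestEpsilonGrid:
    def test_endpoints_count_and_spacing(self):
        g = epsilon_grid()
        assert len(g) == 200
        assert g.values[-1] == pytest.approx(1.0)
        assert g.values[0] == pytest.approx(10 ** -3.98)
        ratios = g.values[1:] / g.values[:-1]
        np.testing.assert_allclose(ratios, 10 ** 0.02, rtol=1e-12)


class TestRipsPersistence:
    def test_single_point(self):
        d = rips_persistence(np.zeros((1, 2)))
        assert d.dgms[0].shape == (1, 2)
        assert np.isinf(d.dgms[0][0, 1])
        assert len(d.dgms[1]) == 0

    def test_two_points(self):
        d = rips_persistence(np.array([[0.0, 0], [0.0, 2.5]]))
        deaths = np.sort(d.dgms[0][:, 1])
        assert deaths[0] == pytest.approx(2.5)
        assert np.isinf(deaths[1])

    def test_unit_square_loop(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        h1 = rips_persistence(pts).dgms[1]
        assert h1.shape == (1, 2)
        assert h1[0, 0] == pytest.approx(1.0)
        assert h1[0, 1] == pytest.approx(np.sqrt(2.0))

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            rips_persistence(np.empty((0, 2)))

    def test_matches_bruteforce_oracle_on_random_clouds(self, rng):
        """Betti curves agree with exact GF(2) boundary-matrix ranks for
        random clouds of up to 7 points at every grid scale."""
        g = epsilon_grid()
        # rescale clouds so distances straddle the grid
        for trial in range(60):
            n = int(rng.integers(1, 8))
            dim = int(rng.integers(1, 4))
            pts = rng.normal(size=(n, dim)) * 10 ** rng.uniform(-4, 0)
            if n > 2 and rng.random() < 0.3:
                pts[1] = pts[0]  # duplicate points
            fast = betti_curves_grid(pts, g)
            orc = oracle_curves(pts, g.values)
            np.testing.assert_array_equal(fast, orc)

    def test_diagram_route_equals_grid_route(self, rng):
        g = epsilon_grid()
        for _ in range(20):
            pts = rng.normal(size=(int(rng.integers(2, 7)), 2)) * 0.1
            d = rips_persistence(pts)
            via = np.array([
                [d.betti_at(e, 0) for e in g.values],
                [d.betti_at(e, 1) for e in g.values],
            ])
            np.testing.assert_array_equal(via, betti_curves_grid(pts, g))

    def test_cohomology_agrees_with_boundary_rank_route(self, rng):
        """Two independent H1 implementations (coboundary reduction with a
        lazy heap vs incremental boundary-matrix rank) agree on mid-size
        clouds in 2 and 4 dimensions."""
        g = epsilon_grid()
        for trial in range(10):
            n = int(rng.integers(15, 40))
            dim = 2 if trial % 2 else 4
            pts = rng.uniform(-0.5, 0.5, (n, dim)) * 10 ** rng.uniform(-3, 0)
            np.testing.assert_array_equal(
                betti_curves_grid(pts, g),
                _betti_curves_via_boundary_reduction(pts, g))

    def test_rigid_motion_and_permutation_invariance(self, rng):
        g = epsilon_grid()
        pts = rng.uniform(-0.2, 0.2, (25, 2))
        base = betti_curves_grid(pts, g)
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pts @ R.T + np.array([0.05, -0.3])
        perm = pts[rng.permutation(25)]
        np.testing.assert_array_equal(betti_curves_grid(moved, g), base)
        np.testing.assert_array_equal(betti_curves_grid(perm, g), base)

    def test_b0_monotone_and_endpoint_values(self, rng):
        g = epsilon_grid()
        pts = rng.uniform(-0.01, 0.01, (30, 2))
        b0 = betti_curves_grid(pts, g)[0]
        assert np.all(np.diff(b0) <= 0)
        from scipy.spatial.distance import pdist
        d = pdist(pts)
        assert b0[g.values < d.min()][-1] == 30 if np.any(
            g.values < d.min()) else True
        assert b0[g.values > d.max()][0] == 1


class TestBettiCurve:
    def test_counts_half_open_intervals(self):
        g = EpsilonGrid(values=np.array([0.5, 1.0, 1.2, 1.5]), delta=0)
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        d = rips_persistence(pts)
        b1 = betti_curve(d, g, 1)
        # loop born at 1, dead at sqrt(2): alive at 1.0 and 1.2 only
        np.testing.assert_array_equal(b1, [0, 1, 1, 0])

    def test_triple_cloud_at_small_scale(self):
        g = EpsilonGrid(values=np.array([1e-2]), delta=0)
        pts = np.array([[0, 0], [1.5, 0], [0, 2.0]])
        b = betti_curves_grid(pts, g)
        assert b[0, 0] == 3 and b[1, 0] == 0


class TestNormalization:
    def test_constant_is_global_sup_norm(self):
        a = np.zeros((2, 3, 2))
        b = np.full((1, 3, 2), -2.0)
        scaled, const = normalize_library([a, b])
        assert const == 2.0
        assert max(np.abs(s).max() for s in scaled) == 1.0

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            normalize_library([])


class TestEmbeddings:
    def _positions(self, n=4, m=2001, seed=0):
        return np.random.default_rng(seed).normal(size=(n, m, 2))

    def test_position_clouds_standard_count(self):
        clouds, idx = position_clouds(self._positions())
        assert clouds.shape == (87, 4, 2)
        assert idx[0] == 22 and idx[-1] == 2000

    def test_time_delay_standard_count_and_dimension(self):
        clouds, idx = time_delay_embed(self._positions())
        assert clouds.shape == (86, 4, 4)
        assert idx[0] == 45  # first downsampled frame dropped
        assert np.all(idx - 5 >= 0)

    def test_static_cloud_distances_scale_by_sqrt2(self):
        pos = np.repeat(np.random.default_rng(2).normal(size=(5, 1, 2)),
                        2001, axis=1)
        clouds, _ = time_delay_embed(pos)
        from scipy.spatial.distance import pdist
        d4 = pdist(clouds[0])
        d2 = pdist(pos[:, 45, :])
        np.testing.assert_allclose(d4, np.sqrt(2) * d2, rtol=1e-12)

    def test_circular_motion_matches_rotation_closed_form(self):
        # agents on a circle rotating rigidly: the 4D delay distance between
        # agents i, j follows from the chord lengths at angles (th_i - th_j)
        # now and at the lag
        n, m, radius, omega = 8, 200, 2.0, 0.6
        dt = 0.05
        t = np.arange(m) * dt
        th0 = 2 * np.pi * np.arange(n) / n
        pos = radius * np.stack([np.cos(th0[:, None] + omega * t),
                                 np.sin(th0[:, None] + omega * t)], axis=2)
        clouds, idx = time_delay_embed(pos, delay_frames=5, stride=23)
        i, j = 0, 3
        dth = th0[i] - th0[j]
        chord = 2 * radius * abs(np.sin(dth / 2))
        # both the current and lagged chord have the same length; the 4D
        # distance is sqrt(2) times it
        got = np.linalg.norm(clouds[0][i] - clouds[0][j])
        assert got == pytest.approx(np.sqrt(2) * chord, rel=1e-12)

    def test_lag_before_start_rejected(self):
        # first used frame is index 45; a lag reaching before t = 0 raises
        with pytest.raises(ValueError):
            time_delay_embed(self._positions(m=100), delay_frames=50,
                             stride=23)

    def test_position_velocity_embedding_scales(self):
        pos = self._positions()
        vel = np.random.default_rng(3).normal(size=pos.shape)
        vmax = np.linalg.norm(vel, axis=2).max()
        clouds, idx = position_velocity_embed(pos, vel, pos_constant=1.0,
                                              vel_constant=vmax)
        assert clouds.shape == (87, 4, 4)
        speeds = np.linalg.norm(clouds[:, :, 2:], axis=2)
        assert speeds.max() <= 1.0 + 1e-12

    def test_zero_velocity_constant_falls_back_to_unit(self):
        pos = self._positions()
        clouds, _ = position_velocity_embed(pos, np.zeros_like(pos),
                                            pos_constant=1.0, vel_constant=0.0)
        assert np.all(clouds[:, :, 2:] == 0.0)


class TestCrocker:
    def test_shapes_for_standard_protocol(self):
        pos = np.random.default_rng(1).normal(size=(5, 2001, 2)) * 0.05
        g = epsilon_grid()
        clouds, idx = position_clouds(pos)
        ck = compute_crockers(clouds, g, max_dim=1, frame_indices=idx)
        assert ck[0].betti.shape == (200, 87)
        assert ck[1].betti.shape == (200, 87)
        clouds4, idx4 = time_delay_embed(pos)
        ck4 = compute_crockers(clouds4, g, max_dim=1, frame_indices=idx4)
        assert ck4[1].betti.shape == (200, 86)

    def test_frozen_sequence_has_identical_columns(self):
        cloud = np.random.default_rng(4).uniform(-0.1, 0.1, (12, 2))
        clouds = np.repeat(cloud[None], 6, axis=0)
        ck = compute_crockers(clouds, epsilon_grid(), max_dim=1)
        for k in (0, 1):
            assert np.all(ck[k].betti == ck[k].betti[:, :1])

    def test_vectorize_lengths_and_round_trip(self):
        pos = np.random.default_rng(1).normal(size=(5, 2001, 2)) * 0.05
        g = epsilon_grid()
        clouds, idx = position_clouds(pos)
        ck = compute_crockers(clouds, g, max_dim=1, frame_indices=idx)
        v0 = vectorize(ck[0])
        assert v0.shape == (200 * 87,)  # 17400
        v01 = vectorize(ck[0], ck[1])
        assert v01.shape == (2 * 200 * 87,)  # 34800
        np.testing.assert_array_equal(v0.reshape(200, 87), ck[0].betti)
        # b0 occupies the first half regardless of argument order
        np.testing.assert_array_equal(vectorize(ck[1], ck[0]), v01)

    def test_vectorize_shape_mismatch_rejected(self):
        pos = np.random.default_rng(1).normal(size=(4, 2001, 2)) * 0.05
        g = epsilon_grid()
        clouds, idx = position_clouds(pos)
        ckp = compute_crockers(clouds, g, frame_indices=idx)
        clouds4, idx4 = time_delay_embed(pos)
        ckd = compute_crockers(clouds4, g, frame_indices=idx4)
        with pytest.raises(ValueError):
            vectorize(ckp[0], ckd[1])
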