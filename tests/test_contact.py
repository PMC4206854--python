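
import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from trichosim import _kernels
from trichosim.contact import (
    CapsuleEdge,
    GeometryError,
    admissible_interactions,
    build_neighbor_list,
    distribute_contact_force,
    edge_pair_forces,
    h_vector,
    line_closest_parameters,
    lj_force_magnitude,
    point_edge_projection,
)


def capsule(x_a, x_b, end_a=True, end_b=True, t_a=None, t_b=None):
    """A free-standing capsule segment: endpoint tangents default to the axis."""
    x_a, x_b = np.asarray(x_a, float), np.asarray(x_b, float)
    axis = (x_b - x_a) / np.linalg.norm(x_b - x_a)
    return CapsuleEdge(x_a, x_b, axis if t_a is None else np.asarray(t_a, float),
                       axis if t_b is None else np.asarray(t_b, float),
                       end_a, end_b)


class TestLineClosestParameters:
    def test_skew_perpendicular(self):
        ab = line_closest_parameters([0, 0, 0], [1, 0, 0],
                                     [0.5, -0.5, 1], [0.5, 0.5, 1])
        assert ab == pytest.approx((0.5, 0.5))
        h = h_vector(np.zeros(3), np.array([1.0, 0, 0]),
                     np.array([0.5, -0.5, 1.0]), np.array([0.5, 0.5, 1.0]),
                     0.5, 0.5)
        assert np.allclose(h, [0, 0, 1])

    def test_parallel_signals_fallback(self):
        assert line_closest_parameters([0, 0, 0], [1, 0, 0],
                                       [0, 1, 0], [1, 1, 0]) is None

    def test_connecting_vector_perpendicular_and_minimal(self, rng):
        for _ in range(200):
            pts = rng.normal(size=(4, 3)) * 2.0
            x1, x2, x3, x4 = pts
            res = line_closest_parameters(x1, x2, x3, x4)
            if res is None:
                continue
            a, b = res
            h = h_vector(x1, x2, x3, x4, a, b)
            d1, d2 = x2 - x1, x4 - x3
            assert abs(h @ d1) < 1e-9 * np.linalg.norm(d1) * max(np.linalg.norm(h), 1)
            assert abs(h @ d2) < 1e-9 * np.linalg.norm(d2) * max(np.linalg.norm(h), 1)
            # grid search around the optimum finds nothing closer
            da = np.linspace(a - 0.05, a + 0.05, 41)
            db = np.linspace(b - 0.05, b + 0.05, 41)
            A, B = np.meshgrid(da, db)
            pts1 = x1[None, :] + A.ravel()[:, None] * d1[None, :]
            pts2 = x3[None, :] + B.ravel()[:, None] * d2[None, :]
            dists = np.linalg.norm(pts2 - pts1, axis=1)
            assert np.linalg.norm(h) <= dists.min() + 1e-12


class TestPointEdgeProjection:
    def test_interior(self):
        assert point_edge_projection([0, 0, 0], [2, 0, 0], [1, 5, 0]) == 0.5

    def test_clamped_low(self):
        assert point_edge_projection([0, 0, 0], [2, 0, 0], [-1, 1, 0]) == 0.0

    def test_clamped_high(self):
        assert point_edge_projection([0, 0, 0], [2, 0, 0], [3, 0, 0]) == 1.0

    def test_degenerate_edge(self):
        with pytest.raises(GeometryError):
            point_edge_projection([0, 0, 0], [0, 0, 0], [1, 0, 0])


class TestAdmissibleInteractions:
    def test_projected_crossing_single_interaction(self):
        e1 = capsule([0, 0, 0], [1, 0, 0])
        e2 = capsule([0.5, -0.5, 1], [0.5, 0.5, 1])
        out = admissible_interactions(e1, e2)
        assert len(out) == 1
        assert (out[0].a, out[0].b) == pytest.approx((0.5, 0.5))
        assert np.allclose(out[0].h_vec, [0, 0, 1])

    def test_end_to_end_gap_single_vertex_contact(self):
        # collinear end-to-end with a gap: the end-cap contact is found once
        # from each side and merged; within force range it is the only one
        theta = 0.15
        e1 = capsule([0, 0, 0], [1, 0, 0])
        e2 = capsule([1.2, 0, 0], [2.2, 0, 0])
        out = [i for i in admissible_interactions(e1, e2) if i.h < 2 * theta]
        assert len(out) == 1
        assert (out[0].a, out[0].b) == (1.0, 0.0)
        assert out[0].h == pytest.approx(0.2)

    def test_parallel_interior_edges_perpendicular_contact(self):
        # interior edges of straight parallel trichomes: the lateral contact
        # vector is perpendicular to both axes
        ax = np.array([1.0, 0, 0])
        e1 = CapsuleEdge(np.array([0.0, 0, 0]), np.array([1.0, 0, 0]),
                         ax, ax, False, False)
        e2 = CapsuleEdge(np.array([0.25, 0.3, 0]), np.array([1.25, 0.3, 0]),
                         ax, ax, False, False)
        out = admissible_interactions(e1, e2)
        assert len(out) >= 1
        for inter in out:
            assert abs(inter.h_vec @ ax) < 1e-12
            assert inter.h == pytest.approx(0.3)

    def test_force_bearing_interactions_almost_always_at_most_two(self, rng):
        # simulator-like geometry: edges of length 4 theta within force range.
        # Nearly parallel overlapping capsules can legitimately touch at 3-4
        # points (both caps plus lateral projections); everywhere else the
        # domain conditions leave at most two force-bearing contacts.
        theta = 1.0
        n_many = 0
        n_total = 20000
        for _ in range(n_total):
            d1, d2 = rng.normal(size=(2, 3))
            d1 *= 4.0 * theta / np.linalg.norm(d1)
            d2 *= 4.0 * theta / np.linalg.norm(d2)
            x1 = np.zeros(3)
            x3 = rng.uniform(-1, 1, 3) * 3.0 * theta
            ends = rng.random(4) < 0.5
            e1 = capsule(x1, x1 + d1, ends[0], ends[1])
            e2 = capsule(x3, x3 + d2, ends[2], ends[3])
            n_force = sum(1 for i in admissible_interactions(e1, e2)
                          if i.h < 2 * theta)
            assert n_force <= 4
            if n_force > 2:
                n_many += 1
        assert n_many / n_total < 0.005

    def test_minimum_h_is_true_segment_distance(self, rng):
        # free-standing capsules: the closest emitted interaction is the true
        # segment-segment distance (dense grid oracle)
        grid = np.linspace(0.0, 1.0, 257)
        A, B = np.meshgrid(grid, grid)
        for _ in range(100):
            pts = rng.normal(size=(4, 3))
            e1 = capsule(pts[0], pts[1])
            e2 = capsule(pts[2], pts[3])
            out = admissible_interactions(e1, e2)
            assert out, "free capsules always admit an interaction"
            hmin = min(i.h for i in out)
            p1 = (pts[0][None, :] + A.ravel()[:, None] * (pts[1] - pts[0])[None, :])
            p2 = (pts[2][None, :] + B.ravel()[:, None] * (pts[3] - pts[2])[None, :])
            oracle = np.linalg.norm(p2 - p1, axis=1).min()
            assert hmin <= oracle + 1e-9
            assert hmin >= oracle - np.linalg.norm(pts[1] - pts[0]) / 128


class TestLJForce:
    def test_zero_at_equilibrium(self):
        assert lj_force_magnitude(1.5, 1.5, 2.0, 1e9) == 0.0

    def test_maximum_attraction(self):
        theta, eps = 1.5, 2.0
        h = (13.0 / 7.0) ** (1.0 / 6.0) * theta
        assert h == pytest.approx(1.1087 * theta, rel=1e-4)
        f = lj_force_magnitude(h, theta, eps, 1e9)
        assert f == pytest.approx(-0.11207 * eps, rel=1e-3)
        # it is the extremum: nearby separations attract less
        assert f < lj_force_magnitude(0.99 * h, theta, eps, 1e9)
        assert f < lj_force_magnitude(1.01 * h, theta, eps, 1e9)

    def test_hard_core_cap(self):
        theta, eps = 1.0, 1.0
        assert lj_force_magnitude(0.5, theta, eps, 1e9) == pytest.approx(
            0.5 * (2**13 - 2**7))
        assert lj_force_magnitude(0.5, theta, eps, 10.0) == 10.0

    def test_truncation(self):
        theta, eps = 1.5, 1.0
        assert lj_force_magnitude(2 * theta, theta, eps, 1e9) == 0.0
        assert lj_force_magnitude(5 * theta, theta, eps, 1e9) == 0.0
        # residual just inside the cutoff is ~3.4 % of the peak attraction
        f_edge = lj_force_magnitude(2 * theta * (1 - 1e-12), theta, eps, 1e9)
        assert abs(f_edge) / 0.11207 == pytest.approx(0.0343, rel=0.01)

    def test_overlap_error(self):
        with pytest.raises(GeometryError):
            lj_force_magnitude(0.0, 1.0, 1.0, 1.0)


class TestDistributeContactForce:
    def test_endpoint_loading(self):
        f = distribute_contact_force(np.array([0, 0, 2.0]), a=0.0, b=1.0)
        assert np.allclose(f[0], [0, 0, 2.0])
        assert np.allclose(f[1], 0.0)
        assert np.allclose(f[3], [0, 0, -2.0])

    def test_interpolation_weights(self):
        f = distribute_contact_force(np.array([0, 0, 1.0]), 0.25, 0.75)
        assert np.allclose(f[:, 2], [0.75, 0.25, -0.25, -0.75])

    def test_zero_net_force_and_torque(self, rng):
        for _ in range(200):
            pts = rng.normal(size=(4, 3))
            a, b = rng.random(2)
            # physical contact force acts along the displacement vector
            hv = h_vector(*pts, a, b)
            fc = rng.normal() * hv
            f = distribute_contact_force(fc, a, b)
            assert np.abs(f.sum(axis=0)).max() < 1e-12 * np.abs(f).max()
            app = np.array([pts[0] + a * (pts[1] - pts[0]),
                            pts[0] + a * (pts[1] - pts[0]),
                            pts[2] + b * (pts[3] - pts[2]),
                            pts[2] + b * (pts[3] - pts[2])])
            torque = np.cross(app, f).sum(axis=0)
            assert np.abs(torque).max() < 1e-12 * max(np.abs(f).max(), 1.0)


class TestEdgePairForces:
    theta = 1.0

    def _pair(self, gap):
        e1 = capsule([0, 0, 0], [4.0, 0, 0])
        e2 = capsule([2.0, gap, -1.0], [2.0, gap, 1.0])
        return e1, e2

    def test_zero_at_equilibrium_separation(self):
        f = edge_pair_forces(*self._pair(self.theta), self.theta, 1.0, 1e9)
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_repulsion_only_suppresses_attraction(self):
        f = edge_pair_forces(*self._pair(1.2 * self.theta), self.theta, 1.0, 1e9,
                             repulsion_only=True, epsilon_repulsion=0.125)
        assert np.allclose(f, 0.0)
        f_att = edge_pair_forces(*self._pair(1.2 * self.theta), self.theta, 1.0, 1e9)
        assert not np.allclose(f_att, 0.0)

    def test_overlap_pushes_apart_symmetrically(self):
        f = edge_pair_forces(*self._pair(0.9 * self.theta), self.theta, 1.0, 1e9)
        # edge 2 sits at +y: edge 1 is pushed to -y, edge 2 to +y
        assert f[:2, 1].sum() < 0
        assert f[2:, 1].sum() > 0
        assert np.abs(f.sum(axis=0)).max() < 1e-12 * np.abs(f).max()

    def test_attraction_pulls_together(self):
        f = edge_pair_forces(*self._pair(1.3 * self.theta), self.theta, 1.0, 1e9)
        assert f[:2, 1].sum() > 0
        assert f[2:, 1].sum() < 0


class TestNeighborList:
    def _random_system(self, rng, n_tri=8, n_seg=6, l=2.0, box=60.0):
        pos = np.zeros((n_tri, n_seg + 1, 3))
        for f in range(n_tri):
            start = rng.uniform(0, box, 3) * [1, 1, 0.05]
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            pos[f] = start + np.arange(n_seg + 1)[:, None] * l * d
        return pos

    def test_far_apart_is_empty(self):
        pos = np.zeros((2, 3, 3))
        pos[0] = [[0, 0, 0], [2, 0, 0], [4, 0, 0]]
        pos[1] = [[0, 50, 0], [2, 50, 0], [4, 50, 0]]
        nl = build_neighbor_list(pos, theta=1.0, l=2.0, width=200.0, depth=200.0)
        assert nl.pairs.shape[0] == 0

    def test_parallel_adjacent_edges_present(self):
        theta, l = 1.0, 2.0
        n = 5
        pos = np.zeros((2, n + 1, 3))
        pos[0, :, 0] = np.arange(n + 1) * l
        pos[1, :, 0] = np.arange(n + 1) * l
        pos[1, :, 1] = 1.5 * theta
        nl = build_neighbor_list(pos, theta, l, 200.0, 200.0)
        pairs = {tuple(p) for p in nl.pairs}
        for e in range(n):
            assert (e, n + e) in pairs  # laterally adjacent edge pairs

    def test_kernel_list_superset_of_reference(self, rng):
        pos = self._random_system(rng, n_tri=10)
        theta, l = 1.0, 2.0
        ref = build_neighbor_list(pos, theta, l, 60.0, 60.0)
        fast = _kernels.build_pairs(pos, 3.0 * theta, 60.0, 60.0, 2)
        fast_set = {tuple(p) for p in fast}
        for p in map(tuple, ref.pairs):
            assert p in fast_set

    def test_staleness_tracking(self, rng):
        pos = self._random_system(rng)
        theta = 1.0
        nl = build_neighbor_list(pos, theta, 2.0, 60.0, 60.0)
        assert not nl.is_stale(pos, theta)
        moved = pos.copy()
        moved[0, 0] += [1.01 * theta, 0, 0]
        assert nl.is_stale(moved, theta)


class TestKernelContactAgreement:
    def test_kernel_matches_reference_pair_forces(self, rng):
        # two-trichome systems with random near-contact geometry; the batched
        # kernel must reproduce the per-pair reference composition
        theta = 1.0
        for _ in range(50):
            pos = np.zeros((2, 4, 3))
            for f in range(2):
                start = rng.uniform(0, 10, 3) * [1, 1, 0.2]
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                pos[f] = start + np.arange(4)[:, None] * 2.0 * d
            pos[1] -= pos[1, 1] - pos[0, 1] - rng.normal(size=3) * theta
            tang = _kernels.batched_tangents(pos)
            pairs = _kernels.build_pairs(pos, 3.0 * theta, 1e3, 1e3, 2)
            out = np.zeros_like(pos)
            _kernels.add_contact_forces(pos, tang, pairs, theta, 2.0, 1e5,
                                        False, 0.25, 1e3, 1e3, out)
            ref = np.zeros_like(pos)
            ne = 3
            for g1, g2 in pairs:
                f1, e1 = divmod(int(g1), ne)
                f2, e2 = divmod(int(g2), ne)
                edge1 = CapsuleEdge(pos[f1, e1], pos[f1, e1 + 1],
                                    tang[f1, e1], tang[f1, e1 + 1],
                                    e1 == 0, e1 + 1 == 3)
                edge2 = CapsuleEdge(pos[f2, e2], pos[f2, e2 + 1],
                                    tang[f2, e2], tang[f2, e2 + 1],
                                    e2 == 0, e2 + 1 == 3)
                ff = edge_pair_forces(edge1, edge2, theta, 2.0, 1e5)
                ref[f1, e1] += ff[0]
                ref[f1, e1 + 1] += ff[1]
                ref[f2, e2] -= -ff[2]
                ref[f2, e2 + 1] -= -ff[3]
            scale = max(np.abs(ref).max(), 1e-12)
            assert np.abs(out - ref).max() < 1e-9 * scale


# ---------------------------------------------------------------------------
# property tests

coords = st.floats(-10.0, 10.0, allow_nan=False, allow_infinity=False, width=64)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.lists(coords, min_size=12, max_size=12),
       st.floats(0.0, 1.0), st.floats(0.0, 1.0),
       st.floats(-3.0, 3.0))
def test_distributed_contact_force_conserves_momentum_and_torque(flat, a, b, s):
    """Any force along the displacement vector, interpolated to the four
    vertices, leaves the pair with zero net force and zero net torque."""
    pts = np.array(flat).reshape(4, 3)
    hv = h_vector(*pts, a, b)
    f = distribute_contact_force(s * hv, a, b)
    scale = max(np.abs(f).max(), 1.0)
    assert np.abs(f.sum(axis=0)).max() <= 1e-9 * scale
    p_on_1 = pts[0] + a * (pts[1] - pts[0])
    p_on_2 = pts[2] + b * (pts[3] - pts[2])
    app = np.array([p_on_1, p_on_1, p_on_2, p_on_2])
    torque = np.cross(app, f).sum(axis=0)
    assert np.abs(torque).max() <= 1e-8 * scale * (1.0 + np.abs(pts).max())


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.lists(coords, min_size=9, max_size=9))
def test_point_edge_projection_is_the_closest_feasible_point(flat):
    """The clamped projection parameter stays in [0, 1] and its point is at
    least as close to the query as either endpoint."""
    pts = np.array(flat).reshape(3, 3)
    xi, xj, xk = pts
    assume(np.linalg.norm(xj - xi) > 1e-6)
    g = point_edge_projection(xi, xj, xk)
    assert 0.0 <= g <= 1.0
    proj = xi + g * (xj - xi)
    d = np.linalg.norm(xk - proj)
    assert d <= np.linalg.norm(xk - xi) + 1e-9
    assert d <= np.linalg.norm(xk - xj) + 1e-9


@settings(derandomize=True, max_examples=300, deadline=None)
@given(st.floats(0.05, 1.999), st.floats(0.0, 5.0))
def test_lj_force_sign_structure(h_over_theta, eps):
    """Repulsive below the contact separation, attractive (bounded) above it,
    out to the truncation radius."""
    theta = 1.5
    f = lj_force_magnitude(h_over_theta * theta, theta, eps, cap_r=1e9)
    if h_over_theta < 1.0:
        assert f >= 0.0
    else:
        assert f <= 0.0
        assert f >= -0.115 * eps  # bounded by the peak attraction
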