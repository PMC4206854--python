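"""Capsule-segment contact: closest-point geometry, LJ force, neighbor lists.

Trichome segments are capsules built on the chain edges.  A pair of edges
``<x1, x2>`` and ``<x3, x4>`` interacts through displacement vectors

    h(a, b) = (b x4 + (1 - b) x3) - (a x2 + (1 - a) x1),   a, b in [0, 1].

If the infinite lines through the edges have their closest approach inside
both segments (a projected crossing), that single vector is the interaction.
Otherwise up to four vertex-against-edge candidates are tested against the
capsule-domain conditions: each vertex's cut plane (normal to the local
tangent) assigns every direction to exactly one of the two segments meeting
there, and chain-end vertices carry a spherical cap that claims the region
beyond the end.  In practice at most two candidates carry force.

Admissible interactions feel a truncated Lennard-Jones force

    f(h) = eps/2 * [(theta/h)^13 - (theta/h)^7],

zero at the equilibrium spacing ``h = theta`` (capsule surfaces touching),
repulsive below it (capped at ``cap_r``), weakly attractive up to the
``2 theta`` truncation radius.  The cohesionless (beta = 0) variant keeps only
the ``h < theta`` hard core, at the strength corresponding to beta = 0.125.

This module is the per-pair reference implementation; the simulation loop uses
an equivalent batched numba kernel that the tests cross-check against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CapsuleEdge",
    "ContactInteraction",
    "NeighborList",
    "line_closest_parameters",
    "point_edge_projection",
    "admissible_interactions",
    "lj_force_magnitude",
    "distribute_contact_force",
    "edge_pair_forces",
    "segment_closest_parameters",
    "build_neighbor_list",
]

#: Relative tolerance below which two edges are treated as parallel.
PARALLEL_TOL = 1e-12


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class CapsuleEdge:
    """One edge with the vertex tangents and chain-end flags of its capsule."""

    x_a: np.ndarray
    x_b: np.ndarray
    t_a: np.ndarray
    t_b: np.ndarray
    end_a: bool = False
    end_b: bool = False


@dataclass(frozen=True)
class ContactInteraction:
    """An admissible contact point pair: parameters and displacement vector."""

    a: float
    b: float
    h_vec: np.ndarray

    @property
    def h(self) -> float:
        return float(np.linalg.norm(self.h_vec))


def h_vector(x1, x2, x3, x4, a: float, b: float) -> np.ndarray:
    """Displacement from the point at ``a`` on edge 1 to the point at ``b`` on edge 2."""
    return (b * x4 + (1.0 - b) * x3) - (a * x2 + (1.0 - a) * x1)


def line_closest_parameters(x1, x2, x3, x4) -> tuple[float, float] | None:
    """Unclamped parameters of the closest points between the two edge lines.

    Returns ``None`` for (near-)parallel edges, signalling fallback to the
    vertex-edge candidates.  For skew lines the connecting vector
    ``h(a, b)`` is perpendicular to both edges.
    """
    d1 = np.asarray(x2, float) - x1
    d2 = np.asarray(x4, float) - x3
    r = np.asarray(x3, float) - x1
    d11 = d1 @ d1
    d22 = d2 @ d2
    d12 = d1 @ d2
    if d11 == 0.0 or d22 == 0.0:
        raise GeometryError("degenerate (zero-length) edge")
    denom = d11 * d22 - d12 * d12
    if denom <= PARALLEL_TOL * d11 * d22:
        return None
    a = ((d1 @ r) * d22 - (d2 @ r) * d12) / denom
    b = ((d1 @ r) * d12 - (d2 @ r) * d11) / denom
    return float(a), float(b)


def point_edge_projection(xi, xj, xk) -> float:
    """Clamped parameter of the closest point on edge ``<xi, xj>`` to ``xk``."""
    d = np.asarray(xj, float) - xi
    dd = d @ d
    if dd == 0.0:
        raise GeometryError("degenerate (zero-length) edge")
    return float(np.clip((np.asarray(xk, float) - xi) @ d / dd, 0.0, 1.0))


def admissible_interactions(e1: CapsuleEdge, e2: CapsuleEdge) -> list[ContactInteraction]:
    """All contact interactions admitted by the capsule domains of two edges.

    A projected crossing yields the single line-line interaction.  Otherwise
    each of the four vertex-edge candidates is kept only when the vertex falls
    in the other edge's axial slab (cut planes at its vertices, widened to the
    spherical cap at chain ends) and the displacement leaves through the
    vertex's own domain half-space.  Coincident candidates (e.g. the
    end-to-end vertex-vertex contact, found once from each side) are merged.
    """
    x1, x2, x3, x4 = e1.x_a, e1.x_b, e2.x_a, e2.x_b
    t1, t2, t3, t4 = e1.t_a, e1.t_b, e2.t_a, e2.t_b
    cross = line_closest_parameters(x1, x2, x3, x4)
    if cross is not None:
        a, b = cross
        if 0.0 < a < 1.0 and 0.0 < b < 1.0:
            return [ContactInteraction(a, b, h_vector(x1, x2, x3, x4, a, b))]

    out: list[ContactInteraction] = []

    def emit(a: float, b: float) -> None:
        for other in out:
            if abs(other.a - a) < 1e-12 and abs(other.b - b) < 1e-12:
                return
        out.append(ContactInteraction(a, b, h_vector(x1, x2, x3, x4, a, b)))

    # Axial-slab conditions select the unique segment of a trichome whose
    # domain contains the opposing vertex; a chain-end vertex carries a
    # spherical cap, claiming in addition exactly the region whose projection
    # clamps onto that end.
    # x3 against edge 1
    a = point_edge_projection(x1, x2, x3)
    if (((x3 - x1) @ t1 >= 0.0 or (e1.end_a and a == 0.0))
            and ((x3 - x2) @ t2 < 0.0 or (e1.end_b and a == 1.0))):
        h1 = h_vector(x1, x2, x3, x4, a, 0.0)
        if h1 @ t3 <= 0.0 or e2.end_a:
            emit(a, 0.0)
    # x4 against edge 1
    a = point_edge_projection(x1, x2, x4)
    if (((x4 - x1) @ t1 >= 0.0 or (e1.end_a and a == 0.0))
            and ((x4 - x2) @ t2 < 0.0 or (e1.end_b and a == 1.0))):
        h2 = h_vector(x1, x2, x3, x4, a, 1.0)
        if h2 @ t4 > 0.0 or e2.end_b:
            emit(a, 1.0)
    # x1 against edge 2
    b = point_edge_projection(x3, x4, x1)
    if (((x1 - x3) @ t3 >= 0.0 or (e2.end_a and b == 0.0))
            and ((x1 - x4) @ t4 < 0.0 or (e2.end_b and b == 1.0))):
        h3 = h_vector(x1, x2, x3, x4, 0.0, b)
        if h3 @ t1 <= 0.0 or e1.end_a:
            emit(0.0, b)
    # x2 against edge 2
    b = point_edge_projection(x3, x4, x2)
    if (((x2 - x3) @ t3 >= 0.0 or (e2.end_a and b == 0.0))
            and ((x2 - x4) @ t4 < 0.0 or (e2.end_b and b == 1.0))):
        h4 = h_vector(x1, x2, x3, x4, 1.0, b)
        if h4 @ t2 > 0.0 or e1.end_b:
            emit(1.0, b)
    return out


def lj_force_magnitude(h: float, theta: float, epsilon: float, cap_r: float) -> float:
    """Signed LJ force magnitude at separation ``h``; positive is repulsive.

    Zero at ``h = theta`` and for ``h >= 2 theta`` (truncation); the repulsive
    branch is capped at ``cap_r`` to bound numerical stiffness.
    """
    if h <= 0.0:
        raise GeometryError(f"overlapping centerlines (h = {h})")
    if h >= 2.0 * theta:
        return 0.0
    q = theta / h
    f = 0.5 * epsilon * (q**13 - q**7)
    return min(f, cap_r)


def distribute_contact_force(fc: np.ndarray, a: float, b: float) -> np.ndarray:
    """Interpolate a contact force to the four edge vertices.

    Vertices 1 and 2 receive ``(1-a) Fc`` and ``a Fc``; vertices 3 and 4 the
    opposite, weighted by ``b``.  Net force and net torque vanish whenever
    ``Fc`` is parallel to the displacement between the application points.
    """
    fc = np.asarray(fc, float)
    return np.array([(1.0 - a) * fc, a * fc, -(1.0 - b) * fc, -b * fc])


def edge_pair_forces(e1: CapsuleEdge, e2: CapsuleEdge, theta: float, epsilon: float,
                     cap_r: float, repulsion_only: bool = False,
                     epsilon_repulsion: float | None = None) -> np.ndarray:
    """Total contact forces on the four vertices of an edge pair (4, 3).

    Composes :func:`admissible_interactions`, :func:`lj_force_magnitude` and
    :func:`distribute_contact_force`.  Under ``repulsion_only`` (the beta = 0
    modification) attraction is suppressed and the hard core uses
    ``epsilon_repulsion``.
    """
    eps = epsilon_repulsion if repulsion_only else epsilon
    if eps is None:
        raise ValueError("repulsion_only mode needs epsilon_repulsion")
    forces = np.zeros((4, 3))
    for inter in admissible_interactions(e1, e2):
        h = inter.h
        if h <= 0.0 or h >= 2.0 * theta:
            continue
        if repulsion_only and h >= theta:
            continue
        f = lj_force_magnitude(h, theta, eps, cap_r)
        # Fc acts on edge 1; repulsive f > 0 must push edge 1 away from edge 2,
        # i.e. along -h_hat (h_vec points from edge 1 to edge 2).
        fc = -f / h * inter.h_vec
        forces += distribute_contact_force(fc, inter.a, inter.b)
    return forces


def segment_closest_parameters(x1, x2, x3, x4) -> tuple[float, float]:
    """Parameters of the true closest points between two segments (clamped)."""
    cross = line_closest_parameters(x1, x2, x3, x4)
    if cross is not None:
        a, b = np.clip(cross[0], 0.0, 1.0), np.clip(cross[1], 0.0, 1.0)
    else:
        a, b = 0.0, point_edge_projection(x3, x4, x1)
    # Alternate clamped projections; converges in two sweeps for segments.
    for _ in range(2):
        p2 = x3 + b * (np.asarray(x4, float) - x3)
        a = point_edge_projection(x1, x2, p2)
        p1 = x1 + a * (np.asarray(x2, float) - x1)
        b = point_edge_projection(x3, x4, p1)
    return float(a), float(b)


def segment_distance(x1, x2, x3, x4) -> float:
    a, b = segment_closest_parameters(x1, x2, x3, x4)
    return float(np.linalg.norm(h_vector(x1, x2, x3, x4, a, b)))


@dataclass
class NeighborList:
    """Candidate edge pairs within the contact cutoff, plus staleness tracking.

    ``pairs`` holds global edge ids (trichome index * n_edges + local index).
    The list is valid (a superset of all truly interacting pairs) until any
    vertex has moved ``theta`` from its position at build time.
    """

    pairs: np.ndarray
    ref_positions: np.ndarray
    cutoff: float

    def is_stale(self, positions: np.ndarray, theta: float) -> bool:
        disp = positions - self.ref_positions
        return bool(np.max(np.einsum("...i,...i->...", disp, disp)) >= theta * theta)


def build_neighbor_list(positions: np.ndarray, theta: float, l: float,
                        width: float, depth: float,
                        exclusion_window: int = 2) -> NeighborList:
    """Reference (all-pairs) neighbor list for positions shaped (F, N+1, 3).

    Includes every edge pair whose true minimum-image segment separation is
    below ``2 theta``, excluding same-trichome pairs with index separation
    ``<= exclusion_window``.  O(pairs^2); the simulation uses a spatial-hash
    kernel with the same contract.
    """
    n_tri, n_vert = positions.shape[0], positions.shape[1]
    n_edges = n_vert - 1
    cutoff = 2.0 * theta
    pairs = []
    box = np.array([width, depth, 0.0])
    for fi in range(n_tri):
        for ei in range(n_edges):
            for fj in range(fi, n_tri):
                ej_start = ei + exclusion_window + 1 if fj == fi else 0
                for ej in range(ej_start, n_edges):
                    p1, p2 = positions[fi, ei], positions[fi, ei + 1]
                    q1, q2 = positions[fj, ej], positions[fj, ej + 1]
                    # minimum image applied to the second edge as a whole
                    mid_delta = 0.5 * (q1 + q2) - 0.5 * (p1 + p2)
                    shift = np.zeros(3)
                    shift[:2] = -np.round(mid_delta[:2] / box[:2]) * box[:2]
                    if segment_distance(p1, p2, q1 + shift, q2 + shift) < cutoff:
                        pairs.append((fi * n_edges + ei, fj * n_edges + ej))
    pairs_arr = (np.array(pairs, dtype=np.int64) if pairs
                 else np.empty((0, 2), dtype=np.int64))
    return NeighborList(pairs=pairs_arr, ref_positions=positions.copy(), cutoff=cutoff)
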