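"""Discrete-elastic-rod bending for naturally straight, torsion-free chains.

A trichome centerline is a chain of vertices ``x_0 .. x_N`` with edges
``e_i = x_{i+1} - x_i``.  Bending is measured per interior vertex by the
discrete curvature binormal

    (kb)_i = 2 (e_{i-1} x e_i) / (|e_{i-1}| |e_i| + e_{i-1} . e_i),

a vector perpendicular to the two adjacent edges whose magnitude is
``2 tan(phi/2)`` for a turning angle ``phi``.  The bending energy of a rod of
modulus ``alpha`` discretised with edge length ``l`` is

    E = (alpha / l) * sum_i |(kb)_i|^2,

and the bending force on each vertex is exactly ``-grad E``.  The gradient is
taken with respect to free vertex positions (edge-norm variation included), so
the forces agree with finite differences of the energy without reference to
the inextensibility constraint; the constraint is enforced separately by the
projection step in :mod:`trichosim.dynamics`.

These are the single-chain reference implementations; the simulation loop uses
batched numba kernels (:mod:`trichosim._kernels`) that are cross-checked
against this module in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "vertex_tangents",
    "curvature_binormal",
    "bending_energy",
    "bending_forces",
]


class DegenerateGeometryError(ValueError):
    """Raised when a chain has coincident vertices or a 180-degree fold."""


def _edges(vertices: np.ndarray) -> np.ndarray:
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 3 or vertices.shape[0] < 2:
        raise ValueError("vertices must be an (n >= 2, 3) array")
    return vertices[1:] - vertices[:-1]


def vertex_tangents(vertices: np.ndarray) -> np.ndarray:
    """Unit tangent at each vertex, oriented from head (x_0) toward tail (x_N).

    Endpoints use their single adjacent edge; interior vertices use the chord
    ``x_{i+1} - x_{i-1}``.  All tangents share one orientation so that a
    polarity sign can be applied uniformly by the gliding force.
    """
    vertices = np.asarray(vertices, dtype=float)
    e = _edges(vertices)
    if np.any(np.linalg.norm(e, axis=1) == 0.0):
        raise DegenerateGeometryError("coincident adjacent vertices")
    t = np.empty_like(vertices)
    t[0] = e[0]
    t[-1] = e[-1]
    if vertices.shape[0] > 2:
        t[1:-1] = vertices[2:] - vertices[:-2]
    norms = np.linalg.norm(t, axis=1)
    if np.any(norms == 0.0):
        raise DegenerateGeometryError("undefined tangent (folded chain)")
    return t / norms[:, None]


def curvature_binormal(vertices: np.ndarray) -> np.ndarray:
    """Discrete curvature binormal at each of the ``n - 2`` interior vertices."""
    e = _edges(vertices)
    if e.shape[0] < 2:
        raise ValueError("need at least 3 vertices")
    u, v = e[:-1], e[1:]
    denom = (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
             + np.einsum("ij,ij->i", u, v))
    if np.any(denom <= 0.0):
        raise DegenerateGeometryError("anti-parallel adjacent edges")
    return 2.0 * np.cross(u, v) / denom[:, None]


def bending_energy(vertices: np.ndarray, alpha: float, l: float) -> float:
    """Bending energy ``(alpha / l) * sum |kb|^2`` (J); zero iff straight."""
    kb = curvature_binormal(vertices)
    return float(alpha / l * np.einsum("ij,ij->", kb, kb))


def bending_forces(vertices: np.ndarray, alpha: float, l: float) -> np.ndarray:
    """Per-vertex bending forces, the exact negative gradient of the energy.

    The chain as a whole carries no net force and no net torque (the energy is
    invariant under rigid motions).
    """
    vertices = np.asarray(vertices, dtype=float)
    n = vertices.shape[0]
    e = _edges(vertices)
    forces = np.zeros_like(vertices)
    if n < 3:
        return forces
    u, v = e[:-1], e[1:]                       # adjacent edge pairs at vertex j
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    denom = nu * nv + np.einsum("ij,ij->i", u, v)
    if np.any(denom <= 0.0):
        raise DegenerateGeometryError("anti-parallel adjacent edges")
    kb = 2.0 * np.cross(u, v) / denom[:, None]
    kb2 = np.einsum("ij,ij->i", kb, kb)
    # (grad_{j-1} kb)^T kb and (grad_{j+1} kb)^T kb, with the edge-norm
    # variation retained so the force is -grad E under free perturbations.
    s = (nv / nu)[:, None] * u + v
    w = (nu / nv)[:, None] * v + u
    g_prev = (-2.0 * np.cross(v, kb) + s * kb2[:, None]) / denom[:, None]
    g_next = (-2.0 * np.cross(u, kb) - w * kb2[:, None]) / denom[:, None]
    g_self = -(g_prev + g_next)
    coeff = 2.0 * alpha / l
    np.add.at(forces, np.arange(0, n - 2), -coeff * g_prev)
    np.add.at(forces, np.arange(1, n - 1), -coeff * g_self)
    np.add.at(forces, np.arange(2, n), -coeff * g_next)
    return forces
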