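"""Equations of motion, constraint projection, adaptive stepping and the run loop.

Overdamped dynamics per vertex:

    dx/dt = (1/zeta) (F_par + F_perp / b),

with the total force the sum of bending, gliding, contact and wall terms.
Time stepping is first-order Euler with step-doubling error control (one full
step versus two half steps; the step is accepted when the maximum vertex
discrepancy is below the absolute accuracy, default 0.1 um) followed by a
projection of every chain back onto its fixed edge length, then polarity
reversal sampling and a neighbor-list staleness check.

Periodic in x and y (minimum image inside the contact kernels; coordinates are
stored unwrapped), hard repulsive walls in z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .core_model import SystemParams
from .gliding import PolarityProcess

__all__ = [
    "SimulationState",
    "Frame",
    "Trajectory",
    "wall_forces",
    "project_velocity",
    "lincs_project",
    "compute_forces",
    "adaptive_euler_step",
    "initialize_system",
    "relax_overlaps",
    "run_simulation",
]

#: Relative bond-length tolerance of the constraint projection.
LINCS_TOL = 1e-6
LINCS_MAX_ITER = 50

#: Largest allowed reversal probability per step (caps dt at 0.05 / omega).
MAX_OMEGA_DT = 0.05


class StepSizeError(RuntimeError):
    """Raised when the adaptive controller underflows its minimum step."""


# ---------------------------------------------------------------------------
# reference single-chain / single-vertex operations


def wall_forces(z: np.ndarray, height: float, theta: float, wall_c: float) -> np.ndarray:
    """Restoring z-force for vertices pressed into the top or bottom wall."""
    z = np.asarray(z, dtype=float)
    lo, hi = 0.5 * theta, height - 0.5 * theta
    return wall_c * (np.where(z > hi, hi - z, 0.0) + np.where(z < lo, lo - z, 0.0))


def project_velocity(force: np.ndarray, tangent: np.ndarray, zeta: float,
                     b_aniso: float) -> np.ndarray:
    """Velocity of one vertex under the anisotropic mobility."""
    force = np.asarray(force, float)
    tangent = np.asarray(tangent, float)
    f_par = (force @ tangent) * tangent
    return (f_par + (force - f_par) / b_aniso) / zeta


def lincs_project(proposed: np.ndarray, l: float, rel_tol: float = LINCS_TOL,
                  max_iter: int = LINCS_MAX_ITER) -> np.ndarray:
    """Project a single proposed chain onto equal bond lengths ``l``.

    Newton iterations on the linearized constraints; each iteration applies
    the minimal (uniform-drag-weighted) least-squares correction obtained from
    the exact tridiagonal Lagrange solve for the chain topology.
    """
    x = np.ascontiguousarray(proposed, dtype=float)[None, :, :].copy()
    ok = _kernels.constraint_project(x, l, rel_tol, max_iter)
    if not ok:
        raise RuntimeError("constraint projection failed to converge")
    return x[0]


# ---------------------------------------------------------------------------
# system state


@dataclass
class SimulationState:
    """Mutable state of a running simulation (SI units)."""

    params: SystemParams
    positions: np.ndarray          # (F, N+1, 3), unwrapped
    polarity: np.ndarray           # (F,), +-1
    t: float = 0.0
    dt: float = 0.0
    reversals: PolarityProcess | None = None
    nl_pairs: np.ndarray | None = None
    nl_ref: np.ndarray | None = None
    n_steps: int = 0
    n_rejected: int = 0
    n_rebuilds: int = 0
    last_error: float = 0.0    # step-doubling estimate of the last accepted step
    gliding_enabled: bool = True
    reversals_enabled: bool = True
    repulsion_only_override: bool | None = None

    @property
    def n_trichomes(self) -> int:
        return self.positions.shape[0]

    @property
    def repulsion_only(self) -> bool:
        if self.repulsion_only_override is not None:
            return self.repulsion_only_override
        return self.params.repulsion_only

    def bond_lengths(self) -> np.ndarray:
        d = np.diff(self.positions, axis=1)
        return np.sqrt(np.einsum("...i,...i->...", d, d))

    def ensure_neighbor_list(self) -> None:
        p = self.params
        if (self.nl_pairs is None or self.nl_ref is None
                or _kernels.max_displacement_sq(self.positions, self.nl_ref)
                >= p.theta**2):
            cutoff = 2.0 * p.theta + p.theta  # force range + one-diameter skin
            self.nl_pairs = _kernels.build_pairs(self.positions, cutoff,
                                                 p.width, p.depth, 2)
            self.nl_ref = self.positions.copy()
            self.n_rebuilds += 1


def _forces_tangents(state: SimulationState,
                     x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    p = state.params
    tangents = _kernels.batched_tangents(x)
    forces = np.zeros_like(x)
    _kernels.add_bending_forces(x, p.alpha, p.l, forces)
    if state.gliding_enabled:
        _kernels.add_gliding_forces(tangents, state.polarity.astype(np.float64),
                                    p.zeta, p.v0, forces)
    _kernels.add_wall_forces(x, p.height, p.theta, p.wall_c, forces)
    max_pen = 0.0
    if state.nl_pairs is not None and state.nl_pairs.shape[0] > 0:
        max_pen = _kernels.add_contact_forces(
            x, tangents, state.nl_pairs, p.theta, p.epsilon, p.cap_r,
            state.repulsion_only, p.epsilon_repulsion, p.width, p.depth, forces)
    return forces, tangents, max_pen


def compute_forces(state: SimulationState,
                   positions: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Total per-vertex forces (bending + gliding + contact + wall).

    Returns ``(forces, max_penetration)`` where the penetration is the largest
    core overlap ``theta - h`` seen among contact interactions.
    """
    x = state.positions if positions is None else positions
    forces, _, max_pen = _forces_tangents(state, x)
    return forces, max_pen


def _velocities(state: SimulationState, x: np.ndarray) -> tuple[np.ndarray, float]:
    p = state.params
    forces, tangents, max_pen = _forces_tangents(state, x)
    return _kernels.project_velocities(forces, tangents, p.zeta, p.b_aniso), max_pen


def _dt_bounds(params: SystemParams) -> tuple[float, float, float]:
    """(dt_init, dt_min, dt_max), all built from scale-covariant quantities."""
    tau = params.theta / params.v0
    dt_max = 50.0 * tau
    if params.omega > 0.0:
        dt_max = min(dt_max, MAX_OMEGA_DT / params.omega)
    return 0.25 * tau, 1e-9 * tau, dt_max


def adaptive_euler_step(state: SimulationState, dt_cap: float = math.inf) -> float:
    """Advance the system by one accepted adaptive Euler step; return its dt.

    Step-doubling error estimate: the difference between one full Euler step
    and two half steps, measured as the maximum vertex displacement
    discrepancy, must not exceed ``abs_accuracy``.  The accepted state is the
    two-half-step solution, projected back onto the bond constraints.
    """
    p = state.params
    dt_init, dt_min, dt_max = _dt_bounds(p)
    if state.dt <= 0.0:
        state.dt = dt_init
    dt = min(state.dt, dt_max, dt_cap)
    tol = p.abs_accuracy
    if state.n_trichomes == 0:    # degenerate but valid: clock still advances
        state.t += dt
        state.n_steps += 1
        return dt

    state.ensure_neighbor_list()
    x = state.positions
    v_full, _ = _velocities(state, x)
    while True:
        x_full = x + dt * v_full
        x_half = x + (0.5 * dt) * v_full
        v_half, _ = _velocities(state, x_half)
        x_two = x_half + (0.5 * dt) * v_half
        diff = x_full - x_two
        err = math.sqrt(float(np.max(np.einsum("...i,...i->...", diff, diff))))
        if err <= tol:
            break
        state.n_rejected += 1
        dt *= max(0.1, 0.9 * math.sqrt(tol / err))
        if dt < dt_min:
            raise StepSizeError(
                f"step size underflow at t={state.t:.6g}s (err={err:.3g} m)")

    if not _kernels.constraint_project(x_two, p.l, LINCS_TOL, LINCS_MAX_ITER):
        raise RuntimeError("constraint projection failed to converge")
    state.positions = x_two
    state.t += dt
    state.n_steps += 1
    state.last_error = err
    if state.reversals_enabled and state.reversals is not None and p.omega > 0.0:
        state.polarity = state.reversals.step(state.polarity, dt)
    # controller update for the next step
    grow = 1.3 if err == 0.0 else min(1.3, 0.9 * math.sqrt(tol / err))
    state.dt = min(max(dt * grow, dt_min), dt_max)
    return dt


# ---------------------------------------------------------------------------
# initialization and relaxation


def initialize_system(params: SystemParams,
                      rng: np.random.Generator | None = None) -> SimulationState:
    """Straight trichomes, random in-plane orientation, center and height.

    The trichome count follows from the volume fraction ``rho``.  Positions
    are laid out unwrapped; the periodic minimum image is applied by the
    contact machinery only.
    """
    seed_seq = np.random.SeedSequence(params.seed)
    init_seq, rev_seq = seed_seq.spawn(2)
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(init_seq))
    n = params.n_trichomes
    m = params.n_segments + 1
    positions = np.zeros((n, m, 3))
    if n > 0:
        centers = np.empty((n, 3))
        centers[:, 0] = rng.uniform(0.0, params.width, n)
        centers[:, 1] = rng.uniform(0.0, params.depth, n)
        centers[:, 2] = rng.uniform(0.5 * params.theta,
                                    params.height - 0.5 * params.theta, n)
        phi = rng.uniform(0.0, 2.0 * math.pi, n)
        direction = np.stack([np.cos(phi), np.sin(phi), np.zeros(n)], axis=1)
        s = (np.arange(m) - (m - 1) / 2.0) * params.l
        positions = centers[:, None, :] + s[None, :, None] * direction[:, None, :]
    polarity = np.where(rng.random(n) < 0.5, -1, 1).astype(np.int64)
    reversals = PolarityProcess(n, params.omega, rev_seq)
    return SimulationState(params=params, positions=positions, polarity=polarity,
                           reversals=reversals)


def max_penetration(state: SimulationState) -> float:
    """Largest core overlap theta - h over current contact interactions (m)."""
    state.ensure_neighbor_list()
    _, pen = compute_forces(state)
    return pen


def relax_overlaps(state: SimulationState, penetration_frac: float = 0.01,
                   max_steps: int = 20000, jam_frac: float = 0.5) -> SimulationState:
    """Drive the initial condition to a steric equilibrium (no gliding).

    Steps the system with propulsion, cohesion and reversals all disabled
    until the deepest contact penetration falls below ``penetration_frac *
    theta`` or stops decreasing.  In dilute systems the first criterion is
    reached; in dense mats of mutually crossing trichomes a mechanical
    equilibrium remains in which bending stiffness balances the soft contact
    core at a small residual penetration, and that plateau is the stopping
    point.  A plateau deeper than ``jam_frac * theta`` (or an exhausted step
    budget) raises: the density is too high to prepare a valid state.
    """
    p = state.params
    threshold = penetration_frac * p.theta
    if state.n_trichomes == 0 or max_penetration(state) < threshold:
        return state
    state.gliding_enabled = False
    state.reversals_enabled = False
    saved_override = state.repulsion_only_override
    state.repulsion_only_override = True
    try:
        best = math.inf
        stalled = 0
        done = False
        for i in range(max_steps):
            adaptive_euler_step(state)
            if i % 5 != 4:
                continue  # penetration costs a force evaluation; poll sparsely
            pen = max_penetration(state)
            if pen < threshold:
                done = True
                break
            if pen < 0.99 * best:
                best = pen
                stalled = 0
            else:
                stalled += 1
            if stalled >= 40:  # ~200 steps without 1 % progress: equilibrium
                if pen > jam_frac * p.theta:
                    raise RuntimeError(
                        f"relaxation jammed at penetration {pen / p.theta:.2f} "
                        "theta; density too high")
                done = True
                break
        if not done:
            raise RuntimeError(
                "overlap relaxation did not converge; density may be too high")
    finally:
        state.gliding_enabled = True
        state.reversals_enabled = True
        state.repulsion_only_override = saved_override
    state.t = 0.0
    state.dt = 0.0
    state.n_steps = 0
    state.n_rejected = 0
    return state


# ---------------------------------------------------------------------------
# trajectory container and run loop


@dataclass(frozen=True)
class Frame:
    """One stored snapshot (SI units, coordinates wrapped by trichome centroid)."""

    time: float
    positions: np.ndarray   # (F, N+1, 3)
    polarity: np.ndarray    # (F,)


@dataclass
class Trajectory:
    """An ordered sequence of frames plus the parameters that produced it."""

    params: SystemParams
    frames: list[Frame] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def __len__(self) -> int:
        return len(self.frames)


def wrap_by_centroid(positions: np.ndarray, width: float, depth: float) -> np.ndarray:
    """Shift each trichome by whole box lengths so its centroid lies in the box.

    Wrapping whole chains (rather than single vertices) keeps edges continuous
    for the geometry-based metrics.
    """
    out = positions.copy()
    if out.shape[0] == 0:
        return out
    cen = out.mean(axis=1)
    out[:, :, 0] -= (np.floor(cen[:, 0] / width) * width)[:, None]
    out[:, :, 1] -= (np.floor(cen[:, 1] / depth) * depth)[:, None]
    return out


def _snapshot(state: SimulationState) -> Frame:
    p = state.params
    return Frame(time=state.t,
                 positions=wrap_by_centroid(state.positions, p.width, p.depth),
                 polarity=state.polarity.copy())


def run_simulation(params: SystemParams, t_end: float,
                   frame_interval: float = 288.0,
                   relax: bool = True,
                   state: SimulationState | None = None,
                   progress_callback=None) -> tuple[Trajectory, SimulationState]:
    """Initialize, relax and integrate to ``t_end``, recording frames.

    Frames are stored at t = 0 (after overlap relaxation) and at every
    multiple of ``frame_interval``; the integrator lands exactly on frame
    times by capping dt.  Fully reproducible from ``params.seed``.
    """
    if t_end <= 0.0:
        raise ValueError("t_end must be positive")
    if frame_interval <= 0.0:
        raise ValueError("frame_interval must be positive")
    if state is None:
        state = initialize_system(params)
        if relax:
            relax_overlaps(state)
    traj = Trajectory(params=params)
    traj.frames.append(_snapshot(state))
    next_frame = frame_interval
    while state.t < t_end - 1e-12:
        adaptive_euler_step(state, dt_cap=min(next_frame, t_end) - state.t)
        if state.t >= next_frame - 1e-9:
            traj.frames.append(_snapshot(state))
            if progress_callback is not None:
                progress_callback(state)
            next_frame += frame_interval
            if next_frame > t_end + 1e-9:
                next_frame = math.inf
    return traj, state
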