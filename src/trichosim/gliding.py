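"""Tangential gliding propulsion and stochastic polarity reversals.

Each trichome glides along its own axis at a target free speed ``v0``, driven
by a tangential force ``F_i = zeta_i v0 P t_i`` at every vertex, where ``P``
is the +-1 polarity.  Composed with the overdamped mobility this propels an
isolated straight trichome at exactly ``v0``.  Polarity reverses as a Bernoulli
event with probability ``omega * dt`` per trichome per accepted step, giving a
mean reversal period ``1 / omega``.
"""

from __future__ import annotations

import numpy as np

from .elasticity import vertex_tangents

__all__ = ["gliding_forces", "sample_reversal", "PolarityProcess"]


def gliding_forces(vertices: np.ndarray, polarity: int, zeta: float,
                   v0: float) -> np.ndarray:
    """Propulsion force ``zeta v0 P t_i`` at every vertex of one chain."""
    if polarity not in (-1, 1):
        raise ValueError(f"polarity must be -1 or +1, got {polarity}")
    return (zeta * v0 * polarity) * vertex_tangents(vertices)


def sample_reversal(polarity: int, omega: float, dt: float, rng) -> int:
    """Advance one trichome's polarity by one step of duration ``dt``.

    Draws exactly one uniform variate; the polarity flips when it falls below
    ``omega * dt``.
    """
    p = omega * dt
    if p >= 1.0:
        raise ValueError(f"omega * dt must be < 1 for valid sampling, got {p}")
    return -polarity if rng.random() < p else polarity


class PolarityProcess:
    """Reversal process for a whole system, one seeded substream per trichome.

    Substreams make the draws independent of trichome iteration order and of
    each other, so trajectories are reproducible even if the update order
    changes.  Draws are consumed one per trichome per accepted step, in blocks
    for speed.
    """

    _BLOCK = 1024

    def __init__(self, n_trichomes: int, omega: float, seed_seq: np.random.SeedSequence):
        self.omega = float(omega)
        children = seed_seq.spawn(n_trichomes)
        self._gens = [np.random.Generator(np.random.PCG64(c)) for c in children]
        self._buf = np.empty((n_trichomes, 0))
        self._pos = 0

    def _refill(self) -> None:
        self._buf = np.stack([g.random(self._BLOCK) for g in self._gens])
        self._pos = 0

    def step(self, polarity: np.ndarray, dt: float) -> np.ndarray:
        """Return the updated +-1 polarity array after one step of length ``dt``."""
        p = self.omega * dt
        if p >= 1.0:
            raise ValueError(f"omega * dt must be < 1, got {p}")
        if not self._gens:
            return polarity
        if self._pos >= self._buf.shape[1]:
            self._refill()
        draws = self._buf[:, self._pos]
        self._pos += 1
        return np.where(draws < p, -polarity, polarity)
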