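"""Parameters, unit conventions and characteristic scales.

Everything downstream of this module works in SI units (m, s, N, Pa, K).
Configuration files and trajectory output use micrometres and seconds for
readability; the conversion happens at the I/O boundary (:mod:`trichosim.io_cli`).

A trichome is a chain of ``n_segments`` straight edges of equal length
``l = lam / n_segments`` gliding in a shallow cuboidal domain.  The physics is
overdamped: per-vertex drag ``zeta`` (slender-body estimate), tangential
propulsion at speed ``v0``, bending stiffness ``alpha`` and a short-range
Lennard-Jones contact force of strength ``epsilon``.  The single emergent
control parameter is the cohesion number ``beta = epsilon / (zeta * v0)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

__all__ = [
    "BOLTZMANN",
    "SystemParams",
    "CharacteristicScales",
    "drag_coefficient",
    "characteristic_scales",
    "alpha_from_persistence",
    "persistence_from_alpha",
    "young_from_alpha",
    "alpha_from_young",
]

#: Exact SI value of the Boltzmann constant (J/K).
BOLTZMANN = 1.380649e-23

#: Default laboratory temperature (K) used for thermal conversions.
LAB_TEMPERATURE = 293.15


class ParameterError(ValueError):
    """Raised for physically inadmissible parameter values."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0.0) or not math.isfinite(value):
            raise ParameterError(f"{name} must be positive and finite, got {value!r}")


def drag_coefficient(mu: float, lam: float, theta: float, n_segments: int,
                     c_shape: float = 0.5) -> float:
    """Per-vertex drag coefficient ``zeta`` (N s/m) of a thin cylinder.

    The slender-body drag of the whole trichome, ``4 pi mu lam /
    (ln(2 lam / theta) + c_shape)``, is shared equally between its
    ``n_segments + 1`` vertices.

    Parameters
    ----------
    mu : viscosity of the embedding medium (Pa s).
    lam : trichome length (m).
    theta : trichome diameter (m).
    n_segments : number of edges per trichome.
    c_shape : order-unity shape constant of the slender-body formula.
    """
    _require_positive(mu=mu, lam=lam, theta=theta, n_segments=n_segments,
                      c_shape=c_shape)
    aspect = 2.0 * lam / theta
    denom = math.log(aspect) + c_shape
    if denom <= 0.0:
        raise ParameterError(
            f"slender-body formula needs ln(2*lam/theta) + c_shape > 0, got {denom}")
    return 4.0 * math.pi * mu * lam / ((n_segments + 1) * denom)


@dataclass(frozen=True)
class CharacteristicScales:
    """Characteristic length, velocity and time of the nondimensional model.

    ``L = sqrt(alpha / (zeta v0))`` is the length at which bending and
    propulsion forces balance, ``V = v0`` and ``T = L / V``.  ``beta`` is the
    dimensionless cohesion strength ``epsilon / (zeta v0)``.
    """

    L: float
    V: float
    T: float
    beta: float


def characteristic_scales(alpha: float, zeta: float, v0: float,
                          epsilon: float = 0.0) -> CharacteristicScales:
    """Derive :class:`CharacteristicScales` from the dimensional parameters."""
    _require_positive(alpha=alpha, zeta=zeta, v0=v0)
    if epsilon < 0.0:
        raise ParameterError(f"epsilon must be >= 0, got {epsilon}")
    drive = zeta * v0
    L = math.sqrt(alpha / drive)
    return CharacteristicScales(L=L, V=v0, T=L / v0, beta=epsilon / drive)


def alpha_from_persistence(xi: float, temperature: float = LAB_TEMPERATURE) -> float:
    """Bending modulus (N m^2) implied by a thermal persistence length ``xi`` (m)."""
    _require_positive(xi=xi, temperature=temperature)
    return BOLTZMANN * temperature * xi


def persistence_from_alpha(alpha: float, temperature: float = LAB_TEMPERATURE) -> float:
    """Thermal persistence length (m) implied by a bending modulus ``alpha``."""
    _require_positive(alpha=alpha, temperature=temperature)
    return alpha / (BOLTZMANN * temperature)


def young_from_alpha(alpha: float, diameter: float, wall_thickness: float) -> float:
    """Young's modulus (Pa) of the cell wall treated as a hollow cylinder.

    With outer radius ``r = diameter / 2`` and wall thickness ``t``,
    ``Y = 4 alpha / (pi (r^4 - (r - t)^4))``.
    """
    _require_positive(alpha=alpha, diameter=diameter, wall_thickness=wall_thickness)
    r = diameter / 2.0
    if wall_thickness >= r:
        raise ParameterError("wall thickness must be smaller than the radius")
    return 4.0 * alpha / (math.pi * (r**4 - (r - wall_thickness) ** 4))


def alpha_from_young(young: float, diameter: float, wall_thickness: float) -> float:
    """Inverse of :func:`young_from_alpha`."""
    _require_positive(young=young, diameter=diameter, wall_thickness=wall_thickness)
    r = diameter / 2.0
    if wall_thickness >= r:
        raise ParameterError("wall thickness must be smaller than the radius")
    return young * math.pi * (r**4 - (r - wall_thickness) ** 4) / 4.0


@dataclass(frozen=True)
class SystemParams:
    """All physical, geometric and numerical parameters of a simulation.

    All quantities are SI.  Defaults reproduce the reference *Pseudanabaena*
    culture conditions: 1.5 um diameter, 750 um long trichomes at 2.5 % volume
    fraction in a shallow 3.5 x 3.5 mm x 7.5 um domain, gliding at 1.3 um/s
    with a mean reversal period of 300 s.

    ``cap_r`` (repulsion cap) and ``wall_c`` (wall stiffness) default to
    ``100 zeta v0`` and ``100 zeta v0 / theta`` respectively when left at 0;
    both are resolved at construction time.
    """

    theta: float = 1.5e-6
    lam: float = 750e-6
    n_segments: int = 125
    alpha: float = 2e-21
    mu: float = 1.0
    c_shape: float = 0.5
    v0: float = 1.3e-6
    omega: float = 1.0 / 300.0
    epsilon: float = 0.0
    b_aniso: float = 2.0
    cap_r: float = 0.0
    wall_c: float = 0.0
    width: float = 3500e-6
    height: float = 7.5e-6
    depth: float = 3500e-6
    rho: float = 0.025
    abs_accuracy: float = 0.1e-6
    temperature: float = LAB_TEMPERATURE
    seed: int = 0

    def __post_init__(self) -> None:
        _require_positive(theta=self.theta, lam=self.lam, alpha=self.alpha,
                          mu=self.mu, c_shape=self.c_shape, v0=self.v0,
                          b_aniso=self.b_aniso, width=self.width,
                          height=self.height, depth=self.depth,
                          abs_accuracy=self.abs_accuracy,
                          temperature=self.temperature)
        if self.n_segments < 2:
            raise ParameterError(f"n_segments must be >= 2, got {self.n_segments}")
        if self.omega < 0.0:
            raise ParameterError(f"omega must be >= 0, got {self.omega}")
        if self.epsilon < 0.0:
            raise ParameterError(f"epsilon must be >= 0, got {self.epsilon}")
        if not (0.0 <= self.rho < 1.0):
            raise ParameterError(f"rho must lie in [0, 1), got {self.rho}")
        if not (self.height < self.width and self.height < self.depth):
            raise ParameterError("the domain must be shallow: height < width, depth")
        # Resolve the force-scale-relative defaults once, eagerly.
        drive = self.zeta * self.v0
        if self.cap_r == 0.0:
            object.__setattr__(self, "cap_r", 100.0 * drive)
        elif self.cap_r < 0.0:
            raise ParameterError(f"cap_r must be positive, got {self.cap_r}")
        if self.wall_c == 0.0:
            object.__setattr__(self, "wall_c", 100.0 * drive / self.theta)
        elif self.wall_c < 0.0:
            raise ParameterError(f"wall_c must be positive, got {self.wall_c}")

    # -- derived quantities -------------------------------------------------

    @property
    def l(self) -> float:
        """Edge (segment) length (m)."""
        return self.lam / self.n_segments

    @property
    def zeta(self) -> float:
        """Per-vertex drag coefficient (N s/m)."""
        return drag_coefficient(self.mu, self.lam, self.theta, self.n_segments,
                                self.c_shape)

    @property
    def scales(self) -> CharacteristicScales:
        return characteristic_scales(self.alpha, self.zeta, self.v0, self.epsilon)

    @property
    def beta(self) -> float:
        """Dimensionless cohesion strength epsilon / (zeta v0)."""
        return self.epsilon / (self.zeta * self.v0)

    @property
    def repulsion_only(self) -> bool:
        """True when the cohesionless (beta = 0) contact modification applies."""
        return self.epsilon == 0.0

    @property
    def epsilon_repulsion(self) -> float:
        """LJ strength of the retained hard core in the cohesionless mode.

        The cohesionless variant keeps the repulsive branch with the strength
        that corresponds to beta = 0.125.
        """
        return 0.125 * self.zeta * self.v0

    @property
    def n_trichomes(self) -> int:
        """Trichome count implied by the volume fraction ``rho``.

        Uses the plain cylinder volume ``pi (theta/2)^2 lam`` (end caps are a
        < 0.1 % correction at the default aspect ratio).
        """
        volume = self.width * self.height * self.depth
        one = math.pi * (self.theta / 2.0) ** 2 * self.lam
        return int(round(self.rho * volume / one))

    def with_beta(self, beta: float) -> "SystemParams":
        """Return a copy with ``epsilon`` set so that the cohesion number is ``beta``."""
        if beta < 0.0:
            raise ParameterError(f"beta must be >= 0, got {beta}")
        return replace(self, epsilon=beta * self.zeta * self.v0)

    def replace(self, **changes) -> "SystemParams":
        return replace(self, **changes)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))
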