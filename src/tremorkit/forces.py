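"""Virtual force fields applied by the haptic device during dynamic tests.

Three load types perturb the subject's hand: a constant force (capped at
5 N, the device's maximum, corresponding to a 500 g load), a linear spring
F = K*X restoring toward the reference point or path (K swept from 0 to
0.0005 N/m during a session), and a virtual mass-spring-damper
F(t) = M*x'' + B*x' + K*x with the printed constants M = 0.05 kg and
B = 0.0015 kg/s.  Forces computed here are the loads felt by the hand;
spring and damper terms oppose the deviation and velocity respectively.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ForceKind",
    "ForceSpec",
    "FORCE_CAP_N",
    "SPRING_K_MAX",
    "DEFAULT_VIRTUAL_MASS",
    "DEFAULT_VISCOUS_B",
    "clamp_force",
    "constant_force",
    "spring_force",
    "msd_force",
    "spring_schedule",
    "integrate_mass_spring",
]

#: Maximum force magnitude the device can render, N.
FORCE_CAP_N = 5.0
#: Upper end of the spring-constant sweep, N/m.
SPRING_K_MAX = 0.0005
#: Printed virtual mass, kg.
DEFAULT_VIRTUAL_MASS = 0.05
#: Printed viscous friction coefficient, kg/s.
DEFAULT_VISCOUS_B = 0.0015


class ForceKind(str, enum.Enum):
    NONE = "none"
    CONSTANT = "constant"
    SPRING = "spring"
    MASS_SPRING_DAMPER = "mass_spring_damper"


@dataclass(frozen=True, eq=False)
class ForceSpec:
    """Parameters of one virtual force field.

    ``direction``, when set, restricts the spring term to that axis (unit
    vector), e.g. a stiffness applied only perpendicular to the movement.
    """

    kind: ForceKind = ForceKind.NONE
    F_const: np.ndarray = field(default_factory=lambda: np.zeros(3))
    K: float = 0.0
    M: float = 0.0
    B: float = 0.0
    direction: Optional[np.ndarray] = None

    def __post_init__(self):
        object.__setattr__(self, "F_const", np.asarray(self.F_const, float))
        if self.K < 0 or self.M < 0 or self.B < 0:
            raise ValueError("K, M and B must be non-negative")
        if self.direction is not None:
            d = np.asarray(self.direction, float)
            n = np.linalg.norm(d)
            if n == 0:
                raise ValueError("direction must be a nonzero vector")
            object.__setattr__(self, "direction", d / n)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ForceSpec):
            return NotImplemented
        same_dir = ((self.direction is None and other.direction is None)
                    or (self.direction is not None and other.direction is not None
                        and np.array_equal(self.direction, other.direction)))
        return (self.kind == other.kind
                and np.array_equal(self.F_const, other.F_const)
                and (self.K, self.M, self.B) == (other.K, other.M, other.B)
                and same_dir)

    # convenience constructors -------------------------------------------
    @staticmethod
    def none() -> "ForceSpec":
        return ForceSpec(ForceKind.NONE)

    @staticmethod
    def constant(F) -> "ForceSpec":
        return ForceSpec(ForceKind.CONSTANT, F_const=np.asarray(F, float))

    @staticmethod
    def spring(K: float, direction=None) -> "ForceSpec":
        return ForceSpec(ForceKind.SPRING, K=K, direction=direction)

    @staticmethod
    def mass_spring_damper(M: float = DEFAULT_VIRTUAL_MASS,
                           B: float = DEFAULT_VISCOUS_B,
                           K: float = 0.0) -> "ForceSpec":
        return ForceSpec(ForceKind.MASS_SPRING_DAMPER, K=K, M=M, B=B)

    def to_dict(self) -> dict:
        d = {"kind": self.kind.value, "F_const": self.F_const.tolist(),
             "K": self.K, "M": self.M, "B": self.B,
             "direction": None if self.direction is None else self.direction.tolist()}
        return d

    @staticmethod
    def from_dict(d: dict) -> "ForceSpec":
        return ForceSpec(ForceKind(d.get("kind", "none")),
                         F_const=np.asarray(d.get("F_const", (0, 0, 0)), float),
                         K=float(d.get("K", 0.0)), M=float(d.get("M", 0.0)),
                         B=float(d.get("B", 0.0)),
                         direction=d.get("direction"))


def clamp_force(F, cap: float = FORCE_CAP_N) -> np.ndarray:
    """Clamp a force vector's magnitude (not per-axis) to ``cap`` newtons."""
    F = np.asarray(F, float)
    mag = np.linalg.norm(F)
    if mag > cap:
        return F * (cap / mag)
    return F.copy()


def constant_force(spec: ForceSpec) -> np.ndarray:
    """The constant load of a dynamic test, clamped to the 5 N device cap."""
    if spec.kind is not ForceKind.CONSTANT:
        raise ValueError("spec.kind must be 'constant'")
    return clamp_force(spec.F_const)


def spring_force(displacement, K: float) -> np.ndarray:
    """Restoring spring load F = K*X directed toward the equilibrium point.

    ``displacement`` is measured from the equilibrium (target point or
    nearest path point), so the returned vector is -K * displacement with
    magnitude K*|X|.
    """
    if K < 0:
        raise ValueError("spring constant K must be non-negative")
    return -K * np.asarray(displacement, float)


def msd_force(x, v, a, spec: ForceSpec) -> np.ndarray:
    """Mass-spring-damper load F = M*a + B*v + K*x.

    The three terms are the inertia of the virtual mass, the viscous
    friction (speed-dependent) and the elastic force (displacement-
    proportional).
    """
    if spec.kind is not ForceKind.MASS_SPRING_DAMPER:
        raise ValueError("spec.kind must be 'mass_spring_damper'")
    return (spec.M * np.asarray(a, float) + spec.B * np.asarray(v, float)
            + spec.K * np.asarray(x, float))


def spring_schedule(n_steps: int, k_max: float = SPRING_K_MAX) -> np.ndarray:
    """Progressive spring-constant sweep: ``n_steps`` values from 0 to ``k_max``.

    The sweep is linear (arithmetic progression) and monotone
    non-decreasing, matching the protocol of progressively stiffening the
    spring within the defined limits.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    return np.linspace(0.0, k_max, n_steps)


def integrate_mass_spring(x0, v0, M: float, K: float, B: float = 0.0,
                          duration: float = 20.0, dt: float = 1e-3,
                          f_ext=None):
    """Integrate M*x'' + B*x' + K*x = f_ext(t) by semi-implicit Euler.

    Returns ``(t, x, v)`` arrays.  The scheme is symplectic for B = 0, so
    the oscillator energy stays bounded (used as the integrator sanity
    check at the simulator's internal step).
    """
    if M <= 0:
        raise ValueError("mass must be positive")
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    x = np.empty(n)
    v = np.empty(n)
    x[0], v[0] = x0, v0
    for i in range(1, n):
        f = 0.0 if f_ext is None else f_ext(t[i - 1])
        a = (f - B * v[i - 1] - K * x[i - 1]) / M
        v[i] = v[i - 1] + dt * a
        x[i] = x[i - 1] + dt * v[i]
    return t, x, v
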