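"""Force environments for planar reaching.

Four force fields are supported, all evaluated pointwise on the hand state
(position relative to the start-circle centre, in metres; velocity in m/s):

* ``VDCF`` -- velocity-dependent curl field, ``F = B1 [[0,-1],[1,0]] v``.
  Perpendicular to the hand velocity, so it perturbs mid-reach but vanishes
  as the hand decelerates at the target (no target error).
* ``LIPF`` -- linearly increasing position-dependent field, ``Fx = -K1 y``.
  Grows with forward distance and is maximal at the target (induces target
  errors).
* ``PSPF`` -- positively skewed position-dependent field,
  ``Fx = -K2 (cos(pi + 40 y) + 1) / (pi + 40 y)^5``, with ``y`` in metres and
  the argument in radians.  Near-zero at start and target, peaking early in
  the reach (no target error).
* ``CPVF`` -- combined field, the LIPF term minus the VDCF term.

Also provided: the partial error clamp (a one-dimensional spring-damper
channel active only over the second half of the movement, y > 75 mm) and the
endpoint lock (a stiff 2-D spring-damper that latches onto the hand position
at the first moment hand speed falls below 20 mm/s).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FieldKind",
    "HandState",
    "FieldSpec",
    "ChannelSpec",
    "EndpointLockSpec",
    "field_force",
    "channel_force",
    "endpoint_lock_step",
    "EXPERIMENT_GAINS",
]


class FieldKind(str, enum.Enum):
    NULL = "NULL"
    VDCF = "VDCF"
    LIPF = "LIPF"
    PSPF = "PSPF"
    CPVF = "CPVF"


@dataclass(frozen=True)
class HandState:
    """Hand kinematic sample: position (m, start-centred, +y toward target),
    velocity (m/s) and time since movement onset (s)."""

    position: np.ndarray
    velocity: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "velocity", np.asarray(self.velocity, dtype=float))

    @property
    def speed(self) -> float:
        return float(np.hypot(*self.velocity))


@dataclass(frozen=True)
class FieldSpec:
    """Parametric description of one force environment.

    Only the gains relevant to ``kind`` are read: VDCF uses ``b1`` (N s/m),
    LIPF uses ``k1`` (N/m), PSPF uses ``k2`` (N/m), CPVF uses ``k1`` and
    ``b1``.
    """

    kind: FieldKind = FieldKind.NULL
    b1: float = 0.0
    k1: float = 0.0
    k2: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "kind", FieldKind(self.kind))
        if min(self.b1, self.k1, self.k2) < 0:
            raise ValueError("field gains must be non-negative")


#: Gains used with human participants (simulation runs use weaker gains).
EXPERIMENT_GAINS = {"b1": 14.0, "k1": 60.0, "k2": 20868.0}


@dataclass(frozen=True)
class ChannelSpec:
    """Partial error clamp: 1-D spring-damper along the straight start->target
    line (x = 0), active only for y > ``activation_y``."""

    stiffness: float = 800.0
    damping: float = 45.0
    activation_y: float = 0.075

    def __post_init__(self):
        if self.stiffness < 0 or self.damping < 0:
            raise ValueError("channel stiffness/damping must be non-negative")


@dataclass(frozen=True)
class EndpointLockSpec:
    """Endpoint lock: stiff 2-D spring-damper engaging (and latching) at the
    first sample with hand speed below ``speed_threshold``."""

    stiffness: float = 500.0
    damping: float = 50.0
    speed_threshold: float = 0.020
    anchor: np.ndarray | None = None
    engaged: bool = False


_CURL = np.array([[0.0, -1.0], [1.0, 0.0]])


def field_force(spec: FieldSpec, state: HandState) -> np.ndarray:
    """Force (N) exerted on the hand by the field at the given state."""
    p, v = state.position, state.velocity
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite hand state: invalid trajectory sample")
    kind = spec.kind
    if kind is FieldKind.NULL:
        return np.zeros(2)
    if kind is FieldKind.VDCF:
        return spec.b1 * (_CURL @ v)
    if kind is FieldKind.LIPF:
        return np.array([-spec.k1 * p[1], 0.0])
    if kind is FieldKind.PSPF:
        a = math.pi + 40.0 * p[1]
        return np.array([-spec.k2 * (math.cos(a) + 1.0) / a**5, 0.0])
    if kind is FieldKind.CPVF:
        lipf = np.array([-spec.k1 * p[1], 0.0])
        vdcf = spec.b1 * (_CURL @ v)
        return lipf - vdcf
    raise ValueError(f"unknown field kind {kind!r}")


def channel_force(spec: ChannelSpec, state: HandState) -> np.ndarray:
    """Partial-error-clamp force; zero outside the activation region."""
    x, y = state.position
    if y <= spec.activation_y:
        return np.zeros(2)
    return np.array([-spec.stiffness * x - spec.damping * state.velocity[0], 0.0])


def endpoint_lock_step(
    spec: EndpointLockSpec, state: HandState
) -> tuple[np.ndarray, EndpointLockSpec]:
    """One per-step evaluation of the endpoint lock.

    Engagement latches: once the hand speed first drops below the threshold
    the lock anchors to the current hand position and stays engaged until
    the end of the trial.
    """
    if not spec.engaged:
        if state.speed < spec.speed_threshold:
            spec = replace(spec, engaged=True, anchor=state.position.copy())
            return np.zeros(2), spec
        return np.zeros(2), spec
    f = -spec.stiffness * (state.position - spec.anchor) - spec.damping * state.velocity
    return f, spec
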