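"""Time-indexed hand kinematics for one reaching trial."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trajectory:
    """One trial's hand path.

    Positions are metres in the start-centred frame (+y toward the target at
    (0, 0.150) m); velocities are m/s.  ``controls`` and ``applied_forces``
    are optional per-sample extras recorded by the simulators; ``motor_cost``
    is the simulator's scalar effort measure for the trial (sum of u'Ru for
    the optimal-control model, average muscle tension for the V-shaped
    model).
    """

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    controls: np.ndarray | None = None
    applied_forces: np.ndarray | None = None
    motor_cost: float = np.nan
    diverged: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        n = len(self.times)
        if self.positions.shape != (n, 2) or self.velocities.shape != (n, 2):
            raise ValueError("inconsistent trajectory array lengths")

    @property
    def speeds(self) -> np.ndarray:
        return np.hypot(self.velocities[:, 0], self.velocities[:, 1])

    def __len__(self) -> int:
        return len(self.times)
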