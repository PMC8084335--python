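"""Flat and hierarchical optimal-feedback-control reaching model.

The arm is a planar point mass whose actuated force follows the motor
command through a first-order muscle lag.  A finite-horizon, time-varying
LQR policy is re-planned on every trial for the *believed* environment: the
controller's internal model of the external field is ``D_hat = alpha * D``,
where ``D`` is the true force matrix of the adaptation field and ``alpha``
(0..1) tracks internal-model adaptation over trials.  The plant is then
rolled out noise-free under the *true* environment; the model/plant mismatch
(1 - alpha) is what produces lateral deviations and target errors.

The hierarchical variant adds a kinematic-plan layer: a directional aim
bias ``phi`` (degrees, clockwise-positive from straight-to-target) enters
the stage cost through the rank-1 projector ``Q_d`` that penalises position
and velocity perpendicular to the aimed direction, weighted by
``exp(-t/tau)`` so the bias shapes only the early movement.  After every
failed trial (|TE| above the target radius) ``phi`` is updated opposite the
endpoint direction error theta, ``phi <- b*phi - r*theta``; after successes
it decays, ``phi <- b*phi``, until the trial's motor cost falls below a
threshold, which freezes the decay (b := 1) and leaves a persistent curved
null trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics
from .fields import (
    ChannelSpec,
    EndpointLockSpec,
    FieldKind,
    FieldSpec,
    HandState,
    channel_force,
    endpoint_lock_step,
    field_force,
)
from .protocols import N_ADAPT, N_DEADAPT, PEC_OFC, SIM_GAINS_OFC, make_schedule
from .trajectory import Trajectory

__all__ = [
    "OfcConfig",
    "BiasState",
    "alpha_schedule",
    "bias_cost_matrix",
    "assemble_stage_costs",
    "plan_policy",
    "simulate_reach",
    "update_bias",
    "run_condition_ofc",
]

N_DEADAPT_RAMP = 30  # de-adaptation trials over which alpha returns to 0
ALPHA_MAX = 0.8


@dataclass(frozen=True)
class OfcConfig:
    """Point-mass plant, cost weights and bias-layer constants.

    The cost magnitudes (``w_pos``, ``w_vel``, ``w_frc``, ``r_u``) are not
    dictated by theory; they were calibrated once so that the null-field
    reach is straight, covers 150 mm in about 400 ms and stops inside the
    7.5 mm target, and they set the scale of the motor-cost gate.
    """

    dt: float = 0.010
    T: float = 0.400
    T_hold: float = 0.050
    sim_duration: float = 0.450
    mass: float = 1.0
    tau_f: float = 0.060  # muscle lag, s
    w_pos: float = 4.0e4
    w_vel: float = 1.0e2
    w_frc: float = 1.0e-2
    w_lat: float = 100.0  # running cost on lateral position error
    w_latv: float = 1.0  # running cost on lateral velocity
    r_u: float = 1.0e-4
    k_p: float = 0.5
    k_v: float = 0.5
    w_bias: float = 3000.0  # overall scale of the bias term (k_p, k_v are relative)
    tau: float = 0.130
    target: tuple[float, float] = (0.0, 0.150)
    target_radius: float = 0.0075
    bias_b: float = 0.95
    bias_r: float = 0.85
    cost_threshold: float = 0.01
    cost_scale: float = 0.080  # scales u'Ru into the gate's units

    @property
    def n_policy(self) -> int:
        return int(round((self.T + self.T_hold) / self.dt))

    @property
    def n_hold_start(self) -> int:
        return int(round(self.T / self.dt))

    @property
    def n_sim(self) -> int:
        return int(round(self.sim_duration / self.dt))


@dataclass(frozen=True)
class BiasState:
    """Directional-bias layer state for the hierarchical variant."""

    phi: float = 0.0  # degrees, clockwise-positive from straight-to-target
    b: float = 0.95
    r: float = 0.85
    active: bool = False
    frozen: bool = False
    cost_threshold: float = 0.01


def alpha_schedule(trial_index: int) -> float:
    """Internal-model knowledge alpha for global trial 1..305.

    Adaptation (1..155): 0.8*log(log(i)+1)/log(log(155)+1), rising from 0
    to 0.8.  De-adaptation (156..185): the mirrored, decreasing schedule
    0.8*[1 - log(log(i-155)+1)/log(log(30)+1)]; 0 thereafter.
    """
    i = int(trial_index)
    if not 1 <= i <= N_ADAPT + N_DEADAPT:
        raise ValueError(f"trial index {i} outside schedule 1..{N_ADAPT + N_DEADAPT}")
    if i <= N_ADAPT:
        return ALPHA_MAX * math.log(math.log(i) + 1) / math.log(math.log(N_ADAPT) + 1)
    j = i - N_ADAPT
    if j <= N_DEADAPT_RAMP:
        return ALPHA_MAX * (
            1.0 - math.log(math.log(j) + 1) / math.log(math.log(N_DEADAPT_RAMP) + 1)
        )
    return 0.0


def bias_cost_matrix(phi_deg: float) -> np.ndarray:
    """Rank-1 projector penalising motion perpendicular to the aim
    direction d(phi); Q_d @ d = 0 by construction."""
    a = math.radians(phi_deg)
    dx, dy = math.sin(a), math.cos(a)  # clockwise-positive from (0, 1)
    return np.array([[dy * dy, -dx * dy], [-dx * dy, dx * dx]])


# ---------------------------------------------------------------------------
# Linear-quadratic machinery.  Augmented state x = [px, py, vx, vy, fx, fy, 1];
# the trailing constant carries the target offset and any feedforward drift.

_NX = 7
_P = np.zeros((2, _NX)); _P[0, 0] = _P[1, 1] = 1.0
_V = np.zeros((2, _NX)); _V[0, 2] = _V[1, 3] = 1.0
_F = np.zeros((2, _NX)); _F[0, 4] = _F[1, 5] = 1.0


def field_matrices(spec: FieldSpec) -> tuple[np.ndarray, np.ndarray]:
    """(D_p, D_v): force = D_p @ p + D_v @ v for the linear fields.

    PSPF has no force matrix (it is nonlinear in y); its internal-model
    prediction is handled as a feedforward drift along the nominal path.
    """
    Dp = np.zeros((2, 2))
    Dv = np.zeros((2, 2))
    if spec.kind in (FieldKind.LIPF, FieldKind.CPVF):
        Dp[0, 1] = -spec.k1
    if spec.kind is FieldKind.VDCF:
        Dv = spec.b1 * np.array([[0.0, -1.0], [1.0, 0.0]])
    if spec.kind is FieldKind.CPVF:
        Dv = -spec.b1 * np.array([[0.0, -1.0], [1.0, 0.0]])
    return Dp, Dv


def _minjerk_y(t: float, T: float, dist: float) -> float:
    s = min(max(t / T, 0.0), 1.0)
    return dist * (10 * s**3 - 15 * s**4 + 6 * s**5)


def _model_step_matrices(cfg: OfcConfig, spec: FieldSpec, alpha: float):
    """Per-stage (A, B) of the believed dynamics (semi-implicit Euler)."""
    dt, m, tf = cfg.dt, cfg.mass, cfg.tau_f
    Dp, Dv = field_matrices(spec)
    n = cfg.n_policy
    A = np.zeros((_NX, _NX))
    # v' = v + dt/m (f + alpha*(Dp p + Dv v) + drift)
    A[2:4, 0:2] = (dt / m) * alpha * Dp
    A[2:4, 2:4] = np.eye(2) + (dt / m) * alpha * Dv
    A[2:4, 4:6] = (dt / m) * np.eye(2)
    # p' = p + dt v'
    A[0:2, :] = dt * A[2:4, :]
    A[0:2, 0:2] += np.eye(2)
    # f' = (1 - dt/tf) f + (dt/tf) u
    A[4:6, 4:6] = (1.0 - dt / tf) * np.eye(2)
    A[6, 6] = 1.0
    B = np.zeros((_NX, 2))
    B[4:6, :] = (dt / tf) * np.eye(2)
    if spec.kind is FieldKind.PSPF and alpha != 0.0:
        # predicted drift along the nominal straight minimum-jerk path
        As = []
        dist = cfg.target[1]
        for k in range(n):
            Ak = A.copy()
            y = _minjerk_y(k * dt, cfg.T, dist)
            fdrift = alpha * field_force(spec, HandState(np.array([0.0, y]), np.zeros(2)))
            Ak[2:4, 6] += (dt / m) * fdrift
            Ak[0:2, 6] += dt * (dt / m) * fdrift
            As.append(Ak)
        return As, B
    return [A] * n, B


def assemble_stage_costs(cfg: OfcConfig, phi_deg: float, bias_active: bool) -> list[np.ndarray]:
    """Per-stage quadratic state costs Q_k, k = 0..n_policy (inclusive of the
    terminal stage).

    Endpoint accuracy terms act at and after T; small running costs on
    lateral position/velocity act throughout (they make the fully-adapted
    controller track the straight line rather than exploit a known field).
    The directional-bias term is added only once the kinematic-plan layer
    has been activated by a failure, weighted by exp(-t/tau)."""
    n = cfg.n_policy
    tx, ty = cfg.target
    Ep = _P.copy(); Ep[0, 6] = -tx; Ep[1, 6] = -ty  # p - target
    end_cost = cfg.w_pos * Ep.T @ Ep + cfg.w_vel * _V.T @ _V + cfg.w_frc * _F.T @ _F
    run_cost = (
        cfg.w_lat * np.outer(_P[0], _P[0]) + cfg.w_latv * np.outer(_V[0], _V[0])
    )
    Qs = []
    Qd = bias_cost_matrix(phi_deg)
    bias_mat = cfg.w_bias * (cfg.k_p * _P.T @ Qd @ _P + cfg.k_v * _V.T @ Qd @ _V)
    for k in range(n + 1):
        Q = run_cost.copy()
        if k >= cfg.n_hold_start:
            Q += end_cost
        if bias_active:
            Q += math.exp(-k * cfg.dt / cfg.tau) * bias_mat
        Qs.append(Q)
    return Qs


@dataclass
class Policy:
    """Time-varying linear feedback law u_k = -L_k @ x_k."""

    L: list[np.ndarray]
    cfg: OfcConfig
    alpha: float
    phi_deg: float

    def control(self, k: int, x: np.ndarray) -> np.ndarray:
        k = min(k, len(self.L) - 1)  # hold the final-stage law past the horizon
        return -self.L[k] @ x


def plan_policy(
    cfg: OfcConfig,
    field_spec: FieldSpec,
    alpha: float = 0.0,
    phi_deg: float = 0.0,
    bias_active: bool = False,
) -> Policy:
    """Finite-horizon LQR for the believed dynamics (D_hat = alpha*D)."""
    As, B = _model_step_matrices(cfg, field_spec, alpha)
    Qs = assemble_stage_costs(cfg, phi_deg, bias_active)
    R = cfg.r_u * np.eye(2)
    S = Qs[-1].copy()
    Ls: list[np.ndarray] = []
    for k in range(cfg.n_policy - 1, -1, -1):
        A = As[k]
        BtS = B.T @ S
        L = np.linalg.solve(R + BtS @ B, BtS @ A)
        S = Qs[k] + A.T @ S @ (A - B @ L)
        if not np.all(np.isfinite(S)):
            raise FloatingPointError("Riccati recursion diverged; invalid cost weights")
        Ls.append(L)
    Ls.reverse()
    return Policy(L=Ls, cfg=cfg, alpha=alpha, phi_deg=phi_deg)


def simulate_reach(
    policy: Policy,
    true_field: FieldSpec,
    clamp: ChannelSpec | None = None,
    lock: EndpointLockSpec | None = None,
    cfg: OfcConfig | None = None,
) -> Trajectory:
    """Roll the plant forward under the true environment, noise-free.

    The controller acts on the exact state (certainty-equivalent estimator
    with noiseless observations); the model/plant mismatch is entirely in
    the field prediction baked into the policy gains.
    """
    cfg = cfg or policy.cfg
    if lock is None:
        lock = EndpointLockSpec()
    dt, m, tf = cfg.dt, cfg.mass, cfg.tau_f
    x = np.zeros(_NX)
    x[6] = 1.0
    n_sim = cfg.n_sim
    times = np.arange(n_sim + 1) * dt
    P = np.zeros((n_sim + 1, 2)); Vl = np.zeros((n_sim + 1, 2))
    U = np.zeros((n_sim + 1, 2)); Fap = np.zeros((n_sim + 1, 2))
    cost = 0.0
    diverged = False
    onset = False  # lock is consulted only after movement onset
    for k in range(n_sim):
        p, v, f = x[0:2], x[2:4], x[4:6]
        state = HandState(p, v, k * dt)
        u = policy.control(k, x)
        if k < cfg.n_policy:
            cost += cfg.r_u * float(u @ u)
        f_env = field_force(true_field, state)
        if clamp is not None:
            f_env = f_env + channel_force(clamp, state)
        onset = onset or state.speed >= lock.speed_threshold
        f_lock, lock = endpoint_lock_step(lock, state) if onset else (np.zeros(2), lock)
        f_tot = f + f_env + f_lock
        v_new = v + (dt / m) * f_tot
        p_new = p + dt * v_new
        f_new = (1.0 - dt / tf) * f + (dt / tf) * u
        x = np.concatenate([p_new, v_new, f_new, [1.0]])
        P[k + 1], Vl[k + 1], U[k], Fap[k] = p_new, v_new, u, f_env
        if np.linalg.norm(p_new) > 1.0 or not np.all(np.isfinite(x)):
            diverged = True
            break
    n_rec = k + 2 if diverged else n_sim + 1
    return Trajectory(
        times=times[:n_rec], positions=P[:n_rec], velocities=Vl[:n_rec],
        controls=U[:n_rec], applied_forces=Fap[:n_rec],
        motor_cost=cost * cfg.cost_scale, diverged=diverged,
    )


def direction_error_deg(endpoint_m: np.ndarray) -> float:
    """theta: signed angle (deg, clockwise-positive) between the straight
    start->target direction and the start->endpoint direction."""
    return math.degrees(math.atan2(endpoint_m[0], endpoint_m[1]))


def update_bias(
    bias: BiasState, theta_deg: float, failed: bool, motor_cost: float
) -> BiasState:
    """Trial-to-trial update of the directional bias.

    Activation latches at the first failure.  The decay is gated by the
    motor cost: while the cost of the just-executed reach is below the
    threshold the forgetting rate is treated as 1 (no decay), which leaves
    a persistent bias once the reach has become cheap; if the cost rises
    above the threshold again (new failures, new field) the decay resumes.
    """
    frozen = motor_cost < bias.cost_threshold
    b_eff = 1.0 if frozen else bias.b
    if failed:
        phi = b_eff * bias.phi - bias.r * theta_deg
        return replace(bias, phi=phi, active=True, frozen=frozen)
    if bias.active:
        return replace(bias, phi=b_eff * bias.phi, frozen=frozen)
    return replace(bias, frozen=frozen)


def run_condition_ofc(
    variant: str,
    condition: str,
    cfg: OfcConfig | None = None,
    keep_trajectories: bool = False,
) -> pd.DataFrame:
    """Simulate the full 155 + 150 trial schedule for one condition.

    ``variant`` is ``"flat"`` (no kinematic-plan layer, phi = 0 throughout)
    or ``"hierarchical"``.  Returns a tidy per-trial table with columns
    trial, phase, te_mm, ld_mm, phi_deg, alpha, cost, valid (and the
    Trajectory objects in ``.attrs["trajectories"]`` when requested).
    """
    if variant not in ("flat", "hierarchical"):
        raise ValueError(f"unknown variant {variant!r}")
    cfg = cfg or OfcConfig()
    sched = make_schedule(condition, gains=SIM_GAINS_OFC, pec=PEC_OFC)
    adapt_phase, deadapt_phase = sched.counted_phases()
    hier = variant == "hierarchical"
    bias = BiasState(b=cfg.bias_b, r=cfg.bias_r, cost_threshold=cfg.cost_threshold)
    rows = []
    trajs = []
    for i in range(1, N_ADAPT + N_DEADAPT + 1):
        in_adapt = i <= N_ADAPT
        phase = adapt_phase if in_adapt else deadapt_phase
        alpha = alpha_schedule(i)
        policy = plan_policy(cfg, adapt_phase.field, alpha=alpha,
                             phi_deg=bias.phi if hier else 0.0,
                             bias_active=hier and bias.active)
        traj = simulate_reach(policy, phase.field, clamp=phase.channel, cfg=cfg)
        rec = metrics.trial_record(traj, trial=i, phase=phase.label)
        failed = abs(rec.te_mm) > metrics.TARGET_SIZE_MM
        rows.append(
            {"trial": i, "phase": phase.label, "te_mm": rec.te_mm, "ld_mm": rec.ld_mm,
             "phi_deg": bias.phi if hier else 0.0, "alpha": alpha,
             "cost": traj.motor_cost, "valid": rec.valid and not traj.diverged}
        )
        if keep_trajectories:
            trajs.append(traj)
        if hier:
            theta = direction_error_deg(metrics.endpoint(traj))
            bias = update_bias(bias, theta, failed, traj.motor_cost)
    out = pd.DataFrame(rows)
    out.attrs["condition"] = condition
    out.attrs["variant"] = variant
    if keep_trajectories:
        out.attrs["trajectories"] = trajs
    return out
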