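"""Flat and hierarchical V-shaped learning model.

A two-joint, six-muscle planar arm (mono-articular shoulder and elbow
flexor/extensor pairs plus a bi-articular pair, constant moment arms,
muscle length linear in joint angles) tracks a desired hand trajectory.
Within a trial the plant runs a feedforward muscle command plus a delayed
reflex proportional to muscle-space error from the desired lengths; across
trials the feedforward command is corrected by the V-shaped learning law

    u'(t) = [u(t) + du(t + phase)]+,
    du(t) = a * [eps(t)]+ + b_l * [-eps(t)]+ - g,      eps = E + g_d * dE/dt,

which increases activation for both stretch and shortening errors (stretch
more strongly, a > b_l > 0) and subtracts a constant deactivation g.  The
muscle error E is the difference between actual and desired muscle lengths.

The flat variant keeps the desired trajectory fixed: a straight minimum-jerk
reach.  The hierarchical variant adds a kinematic-plan layer: the desired
path is a minimum-jerk trajectory through a via-point laterally deflected by
``dx`` at 120 mm along the reach, with ``dx`` updated opposite the previous
trial's target error (dx' = b*dx - r*TE) after failures, decaying (dx' =
b*dx) after successes, and frozen (b := 1) once the motor cost -- average
muscle tension across the six muscles during movement -- falls below a
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import metrics
from .fields import (
    ChannelSpec,
    EndpointLockSpec,
    FieldSpec,
    HandState,
    channel_force,
    endpoint_lock_step,
    field_force,
)
from .protocols import N_ADAPT, N_DEADAPT, PEC_VS, SIM_GAINS_VS, make_schedule
from .trajectory import Trajectory

__all__ = [
    "ArmConfig",
    "VsLearnConfig",
    "DeflectionState",
    "DesiredTrajectory",
    "minjerk_viapoint",
    "straight_minjerk",
    "muscle_error",
    "vshape_update",
    "update_deflection",
    "init_feedforward",
    "simulate_reach_vs",
    "run_condition_vs",
]


@dataclass(frozen=True)
class ArmConfig:
    """Two-link arm and muscle geometry (SI units).

    The shoulder sits at the origin of the arm frame; the reach starts at
    (0, 0.350) m and targets (0, 0.500) m.  Field-frame coordinates (used by
    the force environments and the behavioural metrics) are start-centred.
    """

    l1: float = 0.30
    l2: float = 0.33
    m1: float = 1.93
    m2: float = 1.52
    r1: float = 0.165  # centre of mass along link 1
    r2: float = 0.19
    i1: float = 0.0141  # link inertias about their centres of mass
    i2: float = 0.0188
    joint_damping: tuple = ((0.74, 0.10), (0.10, 0.82))  # N m s/rad
    #: moment arms, 6 muscles x 2 joints, metres; rows: shoulder flexor,
    #: shoulder extensor, elbow flexor, elbow extensor, biarticular
    #: flexor, biarticular extensor
    moment_arms: tuple = (
        (0.040, 0.0),
        (-0.040, 0.0),
        (0.0, 0.025),
        (0.0, -0.025),
        (0.028, 0.028),
        (-0.028, -0.028),
    )
    intrinsic_coef: float = 35.0  # 1/m; visco-elastic gain per Newton of activation
    reflex_gain: float = 6000.0  # N/m; delayed stretch-reflex gain
    reflex_delay: float = 0.060  # s
    g_d: float = 0.08  # s; velocity-error weight (shared with learning law)
    start: tuple = (0.0, 0.350)
    target: tuple = (0.0, 0.500)
    dt: float = 0.002
    T: float = 0.400  # movement duration
    sim_duration: float = 0.650

    @property
    def A(self) -> np.ndarray:
        return np.asarray(self.moment_arms, dtype=float)

    @property
    def B(self) -> np.ndarray:
        return np.asarray(self.joint_damping, dtype=float)


@dataclass(frozen=True)
class VsLearnConfig:
    """V-shaped learning gains (muscle-space errors in metres, commands in
    Newtons of tension): alpha_l > beta_l > 0, gamma_l > 0."""

    alpha_l: float = 4000.0
    beta_l: float = 2000.0
    gamma_l: float = 1.0
    u_base: float = 450.0  # initial co-activation, N per muscle
    smooth: float = 0.080  # s; low-pass window applied to the per-trial update

    def __post_init__(self):
        if not (self.alpha_l > self.beta_l > 0 and self.gamma_l > 0):
            raise ValueError("require alpha_l > beta_l > 0 and gamma_l > 0")


@dataclass(frozen=True)
class DeflectionState:
    """Via-point deflection layer state (metres)."""

    dx: float = 0.0
    b: float = 0.95
    r: float = 0.45
    active: bool = False
    frozen: bool = False
    cost_threshold: float = 445.0  # average muscle tension, N (calibrated to this muscle parameterization)


@dataclass
class DesiredTrajectory:
    """Desired hand path (field frame, metres) and its derivatives."""

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    accelerations: np.ndarray
    t_via: float | None = None


# ---------------------------------------------------------------------------
# Minimum-jerk via-point planning


def _viapoint_coord(x0, xT, xv, T, t1, t):
    """One coordinate of the min-jerk via-point path and its derivatives.

    The optimum of the integrated-squared-jerk problem with an interior
    position constraint is a quintic plus a c*(t-t1)^5_+ term; rest-to-rest
    boundary conditions fix three coefficients, the remaining four follow
    from the end and via constraints.
    """
    M = np.array(
        [
            [T**3, T**4, T**5, (T - t1) ** 5],
            [3 * T**2, 4 * T**3, 5 * T**4, 5 * (T - t1) ** 4],
            [6 * T, 12 * T**2, 20 * T**3, 20 * (T - t1) ** 3],
            [t1**3, t1**4, t1**5, 0.0],
        ]
    )
    rhs = np.array([xT - x0, 0.0, 0.0, xv - x0])
    a3, a4, a5, c = np.linalg.solve(M, rhs)
    dt1 = np.maximum(t - t1, 0.0)
    x = x0 + a3 * t**3 + a4 * t**4 + a5 * t**5 + c * dt1**5
    v = 3 * a3 * t**2 + 4 * a4 * t**3 + 5 * a5 * t**4 + 5 * c * dt1**4
    a = 6 * a3 * t + 12 * a4 * t**2 + 20 * a5 * t**3 + 20 * c * dt1**3
    jerk = 6 * a3 + 24 * a4 * t + 60 * a5 * t**2 + 60 * c * dt1**2
    return x, v, a, jerk


def minjerk_viapoint(start, via, end, T: float, t_via: float | None = None,
                     dt: float = 0.002) -> DesiredTrajectory:
    """Minimum-jerk rest-to-rest trajectory through a via-point.

    When ``t_via`` is None the passage time is chosen to minimise the
    integrated squared jerk (for a via-point on the straight path this
    recovers the straight minimum-jerk reach).
    """
    start = np.asarray(start, float)
    via = np.asarray(via, float)
    end = np.asarray(end, float)
    if np.allclose(start, end) and np.allclose(start, via):
        raise ValueError("degenerate geometry: start, via and end coincide")
    t = np.arange(int(round(T / dt)) + 1) * dt

    def cost(t1):
        j = 0.0
        for k in range(2):
            *_, jk = _viapoint_coord(start[k], end[k], via[k], T, t1, t)
            j += np.trapezoid(jk**2, t)
        return j

    if t_via is None:
        res = minimize_scalar(cost, bounds=(0.15 * T, 0.85 * T), method="bounded",
                              options={"xatol": 1e-4})
        t_via = float(res.x)
    if not 0.0 < t_via < T:
        raise ValueError("via passage time must lie inside (0, T)")
    P = np.zeros((t.size, 2)); V = np.zeros_like(P); Acc = np.zeros_like(P)
    for k in range(2):
        P[:, k], V[:, k], Acc[:, k], _ = _viapoint_coord(start[k], end[k], via[k], T, t_via, t)
    return DesiredTrajectory(times=t, positions=P, velocities=V, accelerations=Acc, t_via=t_via)


def straight_minjerk(start, end, T: float, dt: float = 0.002) -> DesiredTrajectory:
    """Straight rest-to-rest minimum-jerk reach."""
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    t = np.arange(int(round(T / dt)) + 1) * dt
    s = t / T
    j = 10 * s**3 - 15 * s**4 + 6 * s**5
    dj = (30 * s**2 - 60 * s**3 + 30 * s**4) / T
    ddj = (60 * s - 180 * s**2 + 120 * s**3) / T**2
    d = end - start
    return DesiredTrajectory(
        times=t,
        positions=start + np.outer(j, d),
        velocities=np.outer(dj, d),
        accelerations=np.outer(ddj, d),
    )


# ---------------------------------------------------------------------------
# Arm kinematics and dynamics


def _ik(arm: ArmConfig, p_arm: np.ndarray) -> np.ndarray:
    """Inverse kinematics (elbow branch with q2 > 0), arm frame."""
    x, y = p_arm
    d2 = x * x + y * y
    c2 = (d2 - arm.l1**2 - arm.l2**2) / (2 * arm.l1 * arm.l2)
    c2 = np.clip(c2, -1.0, 1.0)
    q2 = np.arccos(c2)
    q1 = np.arctan2(y, x) - np.arctan2(arm.l2 * np.sin(q2), arm.l1 + arm.l2 * np.cos(q2))
    return np.array([q1, q2])


def _fk(arm: ArmConfig, q: np.ndarray) -> np.ndarray:
    return np.array(
        [
            arm.l1 * np.cos(q[0]) + arm.l2 * np.cos(q[0] + q[1]),
            arm.l1 * np.sin(q[0]) + arm.l2 * np.sin(q[0] + q[1]),
        ]
    )


def _jacobian(arm: ArmConfig, q: np.ndarray) -> np.ndarray:
    s1, c1 = np.sin(q[0]), np.cos(q[0])
    s12, c12 = np.sin(q[0] + q[1]), np.cos(q[0] + q[1])
    return np.array(
        [
            [-arm.l1 * s1 - arm.l2 * s12, -arm.l2 * s12],
            [arm.l1 * c1 + arm.l2 * c12, arm.l2 * c12],
        ]
    )


def _inertia(arm: ArmConfig, q2: float) -> np.ndarray:
    c2 = np.cos(q2)
    m11 = (
        arm.i1 + arm.i2 + arm.m1 * arm.r1**2
        + arm.m2 * (arm.l1**2 + arm.r2**2 + 2 * arm.l1 * arm.r2 * c2)
    )
    m12 = arm.i2 + arm.m2 * (arm.r2**2 + arm.l1 * arm.r2 * c2)
    m22 = arm.i2 + arm.m2 * arm.r2**2
    return np.array([[m11, m12], [m12, m22]])


def _coriolis(arm: ArmConfig, q: np.ndarray, qd: np.ndarray) -> np.ndarray:
    h = arm.m2 * arm.l1 * arm.r2 * np.sin(q[1])
    return np.array([-h * qd[1] * (2 * qd[0] + qd[1]), h * qd[0] ** 2])


def desired_joint_series(arm: ArmConfig, desired: DesiredTrajectory):
    """Joint-space image (q, qd, qdd) of the desired hand path."""
    start = np.asarray(arm.start)
    q = np.array([_ik(arm, p + start) for p in desired.positions])
    dt = desired.times[1] - desired.times[0]
    qd = np.gradient(q, dt, axis=0)
    qdd = np.gradient(qd, dt, axis=0)
    return q, qd, qdd


def muscle_lengths(arm: ArmConfig, q) -> np.ndarray:
    """Muscle lengths relative to the start posture: lambda = -A (q - q0)."""
    q_start = _ik(arm, np.asarray(arm.start))
    return -(np.atleast_2d(q) - q_start) @ arm.A.T


def muscle_error(lambda_actual, lambda_desired, g_d: float, dt: float):
    """Movement error E = lambda - lambda0 and the filtered error
    eps = E + g_d * dE/dt (samples x muscles)."""
    la = np.asarray(lambda_actual, float)
    ld = np.asarray(lambda_desired, float)
    if la.shape != ld.shape:
        raise ValueError("muscle-length series must be aligned")
    E = la - ld
    eps = E + g_d * np.gradient(E, dt, axis=0)
    return E, eps


def vshape_update(u: np.ndarray, eps: np.ndarray, cfg: VsLearnConfig,
                  phase_advance: float, dt: float) -> np.ndarray:
    """One trial-to-trial V-shaped update of the feedforward command.

    ``u`` and ``eps`` are (samples x muscles); the correction is read
    ``phase_advance`` seconds ahead of the command it corrects, compensating
    the feedback delay, and smoothed over ``cfg.smooth`` seconds (the
    activation bandwidth -- unfiltered updates make the trial-to-trial loop
    amplify high-frequency error modes).  Output is rectified.
    """
    from scipy.ndimage import uniform_filter1d

    du = cfg.alpha_l * np.maximum(eps, 0.0) + cfg.beta_l * np.maximum(-eps, 0.0) - cfg.gamma_l
    shift = int(round(phase_advance / dt))
    if shift:
        du = np.vstack([du[shift:], np.repeat(du[-1:], shift, axis=0)])
    w = max(int(round(cfg.smooth / dt)), 1)
    if w > 1:
        du = uniform_filter1d(du, w, axis=0)
    return np.maximum(u + du[: len(u)], 0.0)


def update_deflection(state: DeflectionState, te_m: float, failed: bool,
                      motor_cost: float) -> DeflectionState:
    """Trial-to-trial update of the via-point deflection.

    Activation latches at the first failure.  The decay is gated by the
    motor cost: no decay while the just-executed reach is cheaper than the
    threshold (this is what leaves a persistent deflection), and the decay
    resumes if the cost rises above the threshold again.
    """
    frozen = motor_cost < state.cost_threshold
    b_eff = 1.0 if frozen else state.b
    if failed:
        dx = b_eff * state.dx - state.r * te_m
        return replace(state, dx=dx, active=True, frozen=frozen)
    if state.active:
        return replace(state, dx=b_eff * state.dx, frozen=frozen)
    return replace(state, frozen=frozen)


def init_feedforward(arm: ArmConfig, desired: DesiredTrajectory,
                     learn: VsLearnConfig) -> np.ndarray:
    """Feedforward tensions from inverse dynamics of the desired path plus
    uniform co-activation (which adds no net torque: the moment-arm columns
    of each antagonist pair cancel).  Emulates a practised baseline."""
    q, qd, qdd = desired_joint_series(arm, desired)
    A = arm.A
    AtA_inv = np.linalg.inv(A.T @ A)
    T_list = []
    for k in range(len(q)):
        tau = _inertia(arm, q[k, 1]) @ qdd[k] + _coriolis(arm, q[k], qd[k]) + arm.B @ qd[k]
        T_list.append(A @ (AtA_inv @ tau))
    return np.maximum(np.asarray(T_list) + learn.u_base, 0.0)


def simulate_reach_vs(
    u: np.ndarray,
    desired: DesiredTrajectory,
    field_spec: FieldSpec,
    clamp: ChannelSpec | None = None,
    lock: EndpointLockSpec | None = None,
    arm: ArmConfig | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Forward-simulate one trial (noise-free).

    The plant is driven by the feedforward tensions ``u`` (samples x 6, on
    the desired-trajectory time base) plus a delayed reflex proportional to
    the muscle-space error from the desired lengths.  External damping from
    the clamp/lock is integrated implicitly for stability.  Returns the
    hand Trajectory (field frame; ``motor_cost`` = average muscle tension
    over the movement; error and tension series in ``meta``) and the
    tension series.
    """
    arm = arm or ArmConfig()
    if lock is None:
        lock = EndpointLockSpec()
    dt = arm.dt
    n = int(round(arm.sim_duration / dt))
    n_mov = len(desired.times) - 1
    start = np.asarray(arm.start)
    q = _ik(arm, start)
    qd = np.zeros(2)
    q_des, _, _ = desired_joint_series(arm, desired)
    lam_des = muscle_lengths(arm, q_des)
    delay_steps = int(round(arm.reflex_delay / dt))
    A, B = arm.A, arm.B
    E_hist = np.zeros((n + 1, 6))
    P = np.zeros((n + 1, 2)); V = np.zeros((n + 1, 2))
    Ften = np.zeros((n + 1, 6)); Fap = np.zeros((n + 1, 2))
    onset = False
    diverged = False
    k = 0
    for k in range(n):
        p_field = _fk(arm, q) - start
        J = _jacobian(arm, q)
        v_hand = J @ qd
        state = HandState(p_field, v_hand, k * dt)
        kd = min(k, n_mov)
        lam = muscle_lengths(arm, q)[0]
        E_hist[k] = lam - lam_des[kd]
        kdel = max(k - delay_steps, 0)
        Edot_del = (E_hist[kdel] - E_hist[max(kdel - 1, 0)]) / dt
        Edot_now = (E_hist[k] - E_hist[max(k - 1, 0)]) / dt
        reflex = arm.reflex_gain * (E_hist[kdel] + arm.g_d * Edot_del)
        u_k = u[min(k, len(u) - 1)]
        # visco-elasticity scales with activation: co-contraction stiffens
        # the arm, which is what makes the learning loop self-stabilising
        intrinsic = arm.intrinsic_coef * u_k * (E_hist[k] + arm.g_d * Edot_now)
        tension = np.maximum(u_k + intrinsic + reflex, 0.0)
        Ften[k] = tension
        tau_m = A.T @ tension
        f_env = field_force(field_spec, state)
        damp_hand = np.zeros((2, 2))
        if clamp is not None and p_field[1] > clamp.activation_y:
            f_env = f_env + np.array([-clamp.stiffness * p_field[0], 0.0])
            damp_hand[0, 0] += clamp.damping
        onset = onset or state.speed >= lock.speed_threshold
        if onset:
            _, lock = endpoint_lock_step(lock, state)
            if lock.engaged:
                f_env = f_env - lock.stiffness * (p_field - lock.anchor)
                damp_hand += lock.damping * np.eye(2)
        Fap[k] = f_env
        tau_ext = J.T @ f_env
        M = _inertia(arm, q[1])
        B_tot = B + J.T @ damp_hand @ J
        rhs = M @ qd + dt * (tau_m + tau_ext - _coriolis(arm, q, qd))
        qd = np.linalg.solve(M + dt * B_tot, rhs)
        q = q + dt * qd
        P[k + 1] = _fk(arm, q) - start
        V[k + 1] = _jacobian(arm, q) @ qd
        if not np.all(np.isfinite(q)) or np.linalg.norm(P[k + 1]) > 1.0:
            diverged = True
            break
    n_rec = (k + 2) if diverged else (n + 1)
    lam = muscle_lengths(arm, q)[0]
    E_hist[min(n, n_rec - 1)] = lam - lam_des[min(n, n_mov)]
    avg_tension = float(Ften[: n_mov + 1].mean())
    traj = Trajectory(
        times=np.arange(n_rec) * dt, positions=P[:n_rec], velocities=V[:n_rec],
        applied_forces=Fap[:n_rec], motor_cost=avg_tension, diverged=diverged,
        meta={"E": E_hist[:n_rec], "tension": Ften[:n_rec]},
    )
    return traj, Ften[:n_rec]


def _desired_for(arm: ArmConfig, dx: float) -> DesiredTrajectory:
    start = np.zeros(2)
    end = np.array(arm.target) - np.array(arm.start)
    if dx == 0.0:
        return straight_minjerk(start, end, arm.T, arm.dt)
    return minjerk_viapoint(start, np.array([dx, 0.120]), end, arm.T, dt=arm.dt)


def run_condition_vs(
    variant: str,
    condition: str,
    arm: ArmConfig | None = None,
    learn: VsLearnConfig | None = None,
    deflect: DeflectionState | None = None,
) -> pd.DataFrame:
    """Simulate the 155 + 150 trial schedule with the V-shaped learner.

    Returns the same tidy per-trial table as the optimal-control runner
    (``dx_mm`` in place of ``phi_deg``; ``cost`` = average muscle tension).
    """
    if variant not in ("flat", "hierarchical"):
        raise ValueError(f"unknown variant {variant!r}")
    arm = arm or ArmConfig()
    learn = learn or VsLearnConfig()
    hier = variant == "hierarchical"
    state = deflect or DeflectionState()
    sched = make_schedule(condition, gains=SIM_GAINS_VS, pec=PEC_VS)
    adapt_phase, deadapt_phase = sched.counted_phases()
    desired = _desired_for(arm, 0.0)
    # The issued feedforward is the inverse-dynamics image of the *current*
    # kinematic plan plus a learned correction: changing the plan (via-point
    # deflection) takes effect immediately, while field compensation lives
    # in the correction that the V-shaped law updates across trials.
    base = init_feedforward(arm, desired, learn)
    u_corr = np.zeros_like(base)
    mov_samples = len(desired.times)
    rows = []
    for i in range(1, N_ADAPT + N_DEADAPT + 1):
        phase = adapt_phase if i <= N_ADAPT else deadapt_phase
        u = np.maximum(base + u_corr, 0.0)
        traj, _ = simulate_reach_vs(u, desired, phase.field, clamp=phase.channel, arm=arm)
        rec = metrics.trial_record(traj, trial=i, phase=phase.label)
        failed = abs(rec.te_mm) > metrics.TARGET_SIZE_MM
        rows.append(
            {"trial": i, "phase": phase.label, "te_mm": rec.te_mm, "ld_mm": rec.ld_mm,
             "dx_mm": state.dx * 1000.0 if hier else 0.0,
             "cost": traj.motor_cost, "valid": rec.valid and not traj.diverged}
        )
        E_mov = traj.meta["E"][:mov_samples]
        eps = E_mov + arm.g_d * np.gradient(E_mov, arm.dt, axis=0)
        u_corr = vshape_update(u, eps, learn, phase_advance=arm.reflex_delay, dt=arm.dt) - base
        if hier:
            state = update_deflection(state, rec.te_mm / 1000.0, failed, traj.motor_cost)
            desired = _desired_for(arm, state.dx)
            base = init_feedforward(arm, desired, learn)
    out = pd.DataFrame(rows)
    out.attrs["condition"] = condition
    out.attrs["variant"] = variant
    return out
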