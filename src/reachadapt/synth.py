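"""Synthetic multi-participant reaching datasets.

The generator is phenomenological: it is not a third adaptation model but a
fixture factory whose output has the statistical structure the analysis
stages assume.  Per participant, a latent trajectory-plan deflection ``dx``
follows the linear trial-to-trial recursion ``dx' = b*dx - r*TE + noise``
and the observed target error is the field drive (decaying with trials, as
internal-model adaptation would make it) plus the deflection plus trial
noise.  Within-trial hand paths are minimum-jerk in y with a smooth lateral
profile pinned to the trial's LD (at y = 75 mm) and TE (at the endpoint).

Defaults emulate the TE-inducing LIPF condition: first-trial TE of
112.6 +/- 38.0 mm across participants (n = 15), 150 mm reaches of about
400 ms, 7.5 mm target radius, and a de-adaptation after-effect about 40% of
the initial drive with opposite sign.

``fit_update_rule`` recovers (b, r) from observed (TE, dx) series by least
squares, exposed statsmodels-style via :class:`UpdateRuleModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocols import N_ADAPT, N_DEADAPT

__all__ = [
    "GenConfig",
    "gen_te_series",
    "gen_trajectory_dataset",
    "UpdateRuleModel",
    "fit_update_rule",
]


@dataclass(frozen=True)
class GenConfig:
    """Generator parameters (lengths mm, times s)."""

    n_participants: int = 15
    te_mean: float = 112.6  # first-trial |TE| drive across participants
    te_sd: float = 38.0
    b: float = 0.95  # latent-deflection retention
    r: float = 0.45  # latent-deflection sensitivity to TE
    aftereffect_frac: float = 0.4  # de-adaptation drive relative to initial
    ld_drive_frac: float = 0.35  # mid-reach deviation per unit residual drive
    ld_dx_frac: float = 0.6  # mid-reach deviation per unit deflection
    noise_sd: float = 4.0  # observation noise on TE and LD, mm
    dx_noise_sd: float = 1.0  # equation noise inside the latent recursion, mm
    reach_mm: float = 150.0
    duration_s: float = 0.400
    duration_jitter_s: float = 0.020
    dt: float = 0.010
    n_adapt: int = N_ADAPT
    n_deadapt: int = N_DEADAPT


def _rng(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("a seed is required for stochastic generation")
    return np.random.default_rng(seed)


def gen_te_series(cfg: GenConfig, seed) -> pd.DataFrame:
    """Per-trial TE/LD (and the latent deflection) for each participant.

    Each phase is generated by the deflection recursion restarted against a
    constant phase drive (the field push during adaptation; the after-effect,
    about 40% of it with opposite sign, during de-adaptation):

        TE_i = drive + dx_i + obs_noise,
        dx_{i+1} = b*dx_i - r*TE_i + eq_noise,

    so all learning within a phase comes from the recursion (r = 0 and zero
    noise give a flat series) and TE converges geometrically from the
    configured first-trial level towards its fixed point.  LD mixes the
    residual drive with the deflection.  Output is a tidy frame (columns
    participant, trial, phase, te_mm, ld_mm, dx_mm), bit-identical across
    runs for equal (cfg, seed).
    """
    rng = _rng(seed)
    rows = []
    for p in range(cfg.n_participants):
        drive0 = rng.normal(cfg.te_mean, cfg.te_sd)
        trial = 1
        for phase, n, drive in (
            ("adaptation", cfg.n_adapt, drive0),
            ("de_adaptation", cfg.n_deadapt, -cfg.aftereffect_frac * drive0),
        ):
            dx = 0.0
            for _ in range(n):
                te = drive + dx + rng.normal(0.0, cfg.noise_sd)
                ld = (cfg.ld_drive_frac * (drive + dx) + cfg.ld_dx_frac * dx
                      + rng.normal(0.0, cfg.noise_sd))
                rows.append({"participant": p, "trial": trial, "phase": phase,
                             "te_mm": te, "ld_mm": ld, "dx_mm": dx})
                dx = cfg.b * dx - cfg.r * te + rng.normal(0.0, cfg.dx_noise_sd)
                trial += 1
    return pd.DataFrame(rows)


def _minjerk(s: np.ndarray) -> np.ndarray:
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def _trial_path(te_mm, ld_mm, reach_mm, T, dt):
    """One trial's kinematics hitting LD at mid-reach and TE at the end."""
    n = int(round(T / dt))
    t = np.arange(n + 1) * dt
    s = t / T
    j = _minjerk(s)
    dj = (30 * s**2 - 60 * s**3 + 30 * s**4) / T
    y = reach_mm * 1e-3 * j
    vy = reach_mm * 1e-3 * dj
    bump = np.sin(np.pi * s) ** 2
    dbump = 2 * np.sin(np.pi * s) * np.cos(np.pi * s) * np.pi / T
    c = ld_mm - 0.5 * te_mm  # j(0.5) = 0.5, bump(0.5) = 1
    x = 1e-3 * (te_mm * j + c * bump)
    vx = 1e-3 * (te_mm * dj + c * dbump)
    # short stationary tail so the endpoint is read exactly at rest
    n_tail = 5
    t = np.concatenate([t, t[-1] + dt * np.arange(1, n_tail + 1)])
    x = np.concatenate([x, np.full(n_tail, x[-1])])
    y = np.concatenate([y, np.full(n_tail, y[-1])])
    vx = np.concatenate([vx, np.zeros(n_tail)])
    vy = np.concatenate([vy, np.zeros(n_tail)])
    return t, x, y, vx, vy


def gen_trajectory_dataset(
    cfg: GenConfig,
    seed,
    condition: str = "LIPF_NULL",
    short_reach_trials: tuple[tuple[int, int], ...] = (),
    unstable_participant: int | None = None,
) -> pd.DataFrame:
    """Full-schedule trajectory tables for all participants.

    ``short_reach_trials`` injects (participant, trial) pairs whose reach
    stops short of 75 mm (exercising the trial-exclusion rule);
    ``unstable_participant`` injects late de-adaptation LD jumps and an
    outlying last-20 mean for one participant (exercising the
    participant-screening rule).
    """
    series = gen_te_series(cfg, seed)
    rng = _rng((int(seed) + 1) % 2**31)
    short = set(short_reach_trials)
    n_tr = cfg.n_adapt + cfg.n_deadapt
    if unstable_participant is not None:
        mask = series["participant"] == unstable_participant
        late = mask & (series["trial"] > n_tr - 100)
        idx = series.index[late]
        # alternating-sign large LD jumps plus a shifted last-20 mean
        flips = 40.0 * np.where(np.arange(idx.size) % 2 == 0, 1.0, -1.0)
        series.loc[idx, "ld_mm"] = flips
        series.loc[series.index[mask & (series["trial"] > n_tr - 20)], "ld_mm"] += 150.0
    tables = []
    for (p, tr), row in series.set_index(["participant", "trial"]).iterrows():
        T = float(np.clip(cfg.duration_s + rng.normal(0, cfg.duration_jitter_s), 0.3, 0.5))
        reach = 60.0 if (p, tr) in short else cfg.reach_mm
        t, x, y, vx, vy = _trial_path(row["te_mm"], row["ld_mm"], reach, T, cfg.dt)
        tables.append(pd.DataFrame({
            "participant": p, "condition": condition, "phase": row["phase"],
            "trial": tr, "t_s": t, "x_m": x, "y_m": y, "vx_ms": vx, "vy_ms": vy,
            "fx_N": 0.0, "fy_N": 0.0,
        }))
    out = pd.concat(tables, ignore_index=True)
    out.attrs["seed"] = int(seed)
    return out


class UpdateRuleResults:
    """Least-squares estimates of the deflection update rule
    dx[i+1] = b dx[i] - r TE[i]."""

    def __init__(self, sm_results, identifiable: bool):
        self._res = sm_results
        self.identifiable = identifiable
        self.b = float(sm_results.params[0])
        self.r = float(-sm_results.params[1]) if identifiable else np.nan
        self.bse = np.asarray(sm_results.bse, dtype=float)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.b, self.r])

    def summary(self):
        return self._res.summary()

    def __repr__(self):
        flag = "" if self.identifiable else " (r unidentifiable)"
        return f"UpdateRuleResults(b={self.b:.4f}, r={self.r:.4f}){flag}"


class UpdateRuleModel:
    """statsmodels-style wrapper: fit the linear trial-to-trial recursion of
    the kinematic-plan deflection to observed (TE, dx) series."""

    def __init__(self, te_series, dx_series):
        te = np.asarray(te_series, dtype=float)
        dx = np.asarray(dx_series, dtype=float)
        if te.size != dx.size or te.size < 10:
            raise ValueError("need aligned series of at least 10 trials")
        self.endog = dx[1:]
        self.exog = np.column_stack([dx[:-1], te[:-1]])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, te_col="te_mm", dx_col="dx_mm"):
        return cls(df[te_col].to_numpy(), df[dx_col].to_numpy())

    def fit(self) -> UpdateRuleResults:
        import statsmodels.api as sm

        identifiable = np.linalg.matrix_rank(self.exog) == 2
        res = sm.OLS(self.endog, self.exog).fit()
        return UpdateRuleResults(res, identifiable)


def fit_update_rule(te_series, dx_series) -> tuple[float, float]:
    """(b_hat, r_hat) from least squares on the recursion; r_hat is NaN when
    the TE series carries no information (rank-deficient design)."""
    res = UpdateRuleModel(te_series, dx_series).fit()
    return res.b, res.r
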