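"""V-shaped learner: planning, muscle-space errors, updates, arm plant."""

import numpy as np
import pytest

from reachadapt import metrics
from reachadapt.fields import FieldKind, FieldSpec
from reachadapt.protocols import PEC_VS
from reachadapt.vsmodel import (
    ArmConfig,
    DeflectionState,
    VsLearnConfig,
    init_feedforward,
    minjerk_viapoint,
    muscle_error,
    simulate_reach_vs,
    straight_minjerk,
    update_deflection,
    vshape_update,
)

NULL = FieldSpec(kind=FieldKind.NULL)
LIPF = FieldSpec(kind=FieldKind.LIPF, k1=120.0)


class TestViaPointPlanning:
    def test_via_on_straight_line_recovers_straight_reach(self):
        d = minjerk_viapoint((0, 0), (0.0, 0.12), (0, 0.15), T=0.4)
        assert np.abs(d.positions[:, 0]).max() < 1e-9

    @pytest.mark.parametrize("dx", [-0.03, 0.005, 0.02])
    def test_via_point_interpolated_exactly(self, dx):
        d = minjerk_viapoint((0, 0), (dx, 0.12), (0, 0.15), T=0.4, t_via=0.26)
        i = int(round(0.26 / 0.002))
        np.testing.assert_allclose(d.positions[i], (dx, 0.12), atol=1e-12)

    def test_deflection_single_interior_extremum(self):
        d = minjerk_viapoint((0, 0), (0.02, 0.12), (0, 0.15), T=0.4)
        x = d.positions[:, 0]
        assert x.max() > 0.019  # deflects toward +x
        sign_changes = np.sum(np.abs(np.diff(np.sign(np.diff(x[np.abs(x) > 1e-12])))) > 0)
        assert sign_changes <= 2

    def test_rest_to_rest_boundary_conditions(self):
        d = minjerk_viapoint((0, 0), (0.02, 0.12), (0, 0.15), T=0.4)
        np.testing.assert_allclose(d.positions[0], (0, 0), atol=1e-12)
        np.testing.assert_allclose(d.positions[-1], (0, 0.15), atol=1e-9)
        np.testing.assert_allclose(d.velocities[0], 0, atol=1e-9)
        np.testing.assert_allclose(d.velocities[-1], 0, atol=1e-7)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            minjerk_viapoint((0, 0), (0, 0), (0, 0), T=0.4)
        with pytest.raises(ValueError):
            minjerk_viapoint((0, 0), (0.01, 0.12), (0, 0.15), T=0.4, t_via=0.5)


class TestMuscleError:
    def test_zero_when_tracking_is_perfect(self):
        lam = np.random.default_rng(0).normal(size=(50, 6))
        E, eps = muscle_error(lam, lam, g_d=0.1, dt=0.01)
        np.testing.assert_allclose(E, 0.0)
        np.testing.assert_allclose(eps, 0.0)

    def test_constant_offset_passes_through(self):
        lam0 = np.zeros((50, 6))
        E, eps = muscle_error(lam0 + 0.004, lam0, g_d=0.37, dt=0.01)
        np.testing.assert_allclose(E, 0.004)
        np.testing.assert_allclose(eps, 0.004)  # derivative term vanishes

    def test_ramp_error_adds_velocity_term(self):
        t = np.arange(100) * 0.01
        lam = np.tile(t[:, None], (1, 6))
        E, eps = muscle_error(lam, np.zeros_like(lam), g_d=0.1, dt=0.01)
        np.testing.assert_allclose(eps[1:-1], E[1:-1] + 0.1, atol=1e-9)

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError):
            muscle_error(np.zeros((10, 6)), np.zeros((11, 6)), g_d=0.1, dt=0.01)


class TestVShapeUpdate:
    CFG = VsLearnConfig(alpha_l=0.5, beta_l=0.25, gamma_l=0.1, smooth=0.0)

    def test_stretch_error_update(self):
        u = np.zeros((20, 6))
        eps = np.ones((20, 6))
        u2 = vshape_update(u, eps, self.CFG, phase_advance=0.0, dt=0.01)
        np.testing.assert_allclose(u2, 0.4)  # 0.5*1 - 0.1

    def test_shortening_error_update(self):
        u = np.zeros((20, 6))
        u2 = vshape_update(u, -np.ones((20, 6)), self.CFG, phase_advance=0.0, dt=0.01)
        np.testing.assert_allclose(u2, 0.15)  # 0.25*1 - 0.1

    def test_pure_deactivation_rectified_at_zero(self):
        u = np.zeros((20, 6))
        u2 = vshape_update(u, np.zeros((20, 6)), self.CFG, phase_advance=0.0, dt=0.01)
        np.testing.assert_allclose(u2, 0.0)

    def test_commands_stay_nonnegative_under_random_updates(self, rng):
        u = rng.uniform(0, 2, size=(50, 6))
        for _ in range(20):
            eps = rng.normal(0, 3, size=(50, 6))
            u = vshape_update(u, eps, self.CFG, phase_advance=0.02, dt=0.01)
            assert (u >= 0).all()

    def test_phase_advance_shifts_correction_earlier(self):
        cfg = VsLearnConfig(alpha_l=1.0, beta_l=0.5, gamma_l=1e-9, smooth=0.0)
        eps = np.zeros((10, 1))
        eps[6] = 1.0  # error occurs late
        u2 = vshape_update(np.zeros((10, 1)), eps, cfg, phase_advance=0.02, dt=0.01)
        assert u2[4, 0] == pytest.approx(1.0, abs=1e-6)  # correction lands 2 samples earlier
        assert u2[6, 0] == pytest.approx(0.0, abs=1e-6)


class TestDeflectionUpdate:
    def test_failure_update(self):
        s = update_deflection(DeflectionState(), te_m=0.10, failed=True, motor_cost=1e4)
        assert s.dx == pytest.approx(-0.045)  # -0.45 * 0.10
        assert s.active

    def test_success_decay_above_gate(self):
        s = DeflectionState(dx=0.05, active=True)
        s2 = update_deflection(s, te_m=0.0, failed=False, motor_cost=1e4)
        assert s2.dx == pytest.approx(0.0475)

    def test_cheap_reach_stops_decay(self):
        s = DeflectionState(dx=0.05, active=True)
        s2 = update_deflection(s, te_m=0.0, failed=False, motor_cost=100.0)
        assert s2.dx == pytest.approx(0.05)
        assert s2.frozen

    def test_constant_te_converges_to_closed_form_fixed_point(self):
        b, r, te = 0.95, 0.45, 0.02
        s = DeflectionState(b=b, r=r, active=True)
        seq = []
        for _ in range(400):
            s = update_deflection(s, te_m=te, failed=True, motor_cost=1e4)
            seq.append(s.dx)
        fix = -r * te / (1 - b)
        assert seq[-1] == pytest.approx(fix, rel=1e-4)
        # geometric approach: error ratio ~ b each step
        errs = np.abs(np.array(seq[-10:]) - fix)
        ratios = errs[1:] / errs[:-1]
        np.testing.assert_allclose(ratios, b, atol=0.01)


class TestArmPlant:
    def test_converged_null_reach_hits_target(self):
        arm = ArmConfig()
        learn = VsLearnConfig()
        des = straight_minjerk((0, 0), (0, 0.15), arm.T, arm.dt)
        u = init_feedforward(arm, des, learn)
        traj, tensions = simulate_reach_vs(u, des, NULL, arm=arm)
        assert not traj.diverged
        end = metrics.endpoint(traj)
        assert np.linalg.norm(end - [0, 0.150]) < 0.0075
        assert (tensions >= 0).all()

    def test_naive_command_fails_in_lipf(self):
        arm = ArmConfig()
        des = straight_minjerk((0, 0), (0, 0.15), arm.T, arm.dt)
        u = init_feedforward(arm, des, VsLearnConfig())
        traj, _ = simulate_reach_vs(u, des, LIPF, arm=arm)
        assert metrics.target_error(traj) < -metrics.TARGET_RADIUS_MM

    def test_partial_clamp_attenuates_aftereffect(self, vs_runs):
        # first de-adaptation trial: clamped TE is a fraction of unclamped
        te_clamped = abs(vs_runs[("hierarchical", "LIPF_PEC")].te_mm.iloc[155])
        te_free = abs(vs_runs[("hierarchical", "LIPF_NULL")].te_mm.iloc[155])
        assert te_clamped < 0.25 * te_free
        assert te_clamped < metrics.TARGET_SIZE_MM

    def test_learning_reduces_tracking_error_on_nominal_plant(self):
        # start from co-activation only (no inverse-dynamics feedforward):
        # repeated V-shaped updates must drive the muscle error down
        arm = ArmConfig()
        learn = VsLearnConfig()
        des = straight_minjerk((0, 0), (0, 0.15), arm.T, arm.dt)
        n_mov = len(des.times)
        u = np.full((n_mov, 6), learn.u_base, dtype=float)
        errs = []
        for _ in range(25):
            traj, _ = simulate_reach_vs(u, des, NULL, arm=arm)
            E = traj.meta["E"][:n_mov]
            errs.append(np.abs(E).max())
            eps = E + arm.g_d * np.gradient(E, arm.dt, axis=0)
            u = vshape_update(u, eps, learn, phase_advance=arm.reflex_delay, dt=arm.dt)
        errs = np.array(errs)
        assert errs[-1] < 0.5 * errs[0]
        assert np.all(np.diff(errs) < 1e-5)  # decreasing throughout


class TestConditionRunsVs:
    def test_full_schedule_and_validity(self, vs_runs):
        for df in vs_runs.values():
            assert len(df) == 305
            assert df.valid.all()

    def test_flat_and_hierarchical_identical_without_failures(self, vs_runs):
        a = vs_runs[("flat", "VDCF")]
        b = vs_runs[("hierarchical", "VDCF")]
        np.testing.assert_allclose(a.te_mm, b.te_mm, atol=1e-9)
        np.testing.assert_allclose(a.ld_mm, b.ld_mm, atol=1e-9)
        assert (b.dx_mm == 0).all()

    def test_hierarchical_lipf_ld_is_nonmonotone_te_monotone(self, vs_runs):
        df = vs_runs[("hierarchical", "LIPF_NULL")]
        ad = df[df.phase == "adaptation"]
        assert ad.ld_mm.iloc[0] < 0 < ad.ld_mm.iloc[2:15].max()  # sign reversal
        te = ad.te_mm.abs().to_numpy()
        assert np.all(np.diff(te[:30]) <= 0.5)  # early decay, no re-growth
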