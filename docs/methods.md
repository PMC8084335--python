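# Methods

This note documents the models, parameter choices and numerical decisions
behind `reachadapt`, in the spirit of a model-description appendix.

## Task geometry and behavioural measures

Reaches go from the start-circle centre (origin) to the target at
(0, 150) mm, nominally in 400 ms; the target circle is 15 mm across
(radius 7.5 mm).  The movement endpoint is the hand position at the first
sample after movement onset where hand speed drops below 20 mm/s — the
same event that triggers the endpoint lock (a 500 N/m / 50 N·s/m 2-D
spring–damper that latches onto the hand so the trial cannot be rescued
by corrective sub-movements).  TE is the signed x at that endpoint; LD is
the signed x at the first crossing of y = 75 mm (linear interpolation
between bracketing samples).  First-crossing rules are used for both
because trajectories need not be monotone in y and the online lock also
latches at the first crossing.

Two thresholds coexist deliberately.  Statistical summaries compare |TE|
against the 7.5 mm target *radius* (the convention used when reporting
whether endpoint errors exceed the target).  The kinematic-plan layer's
*failure* criterion, however, uses the full 15 mm target circle
(`metrics.TARGET_SIZE_MM`): an endpoint error of ~8 mm still overlaps the
target and is not treated as a failure.  This matters in the partial
error clamp, where the residual after-effect on the first clamped trial
is ~7–8 mm in both models (and of the same order in human data); reading
failure at the radius would spuriously re-activate the plan layer in
exactly the condition designed to suppress failures.

Trials whose reach distance is under 75 mm are excluded (LD undefined).
Participant screening passes when |mean LD| over the last 20 baseline
trials is below 4.5 mm (strict).  The instability flag requires both at
least three consecutive-trial LD sign changes with |ΔLD| > 20 mm over the
last 100 washout trials *and* a last-20 LD mean outside 3 s.d. of the
group mean; a "jump across the x-axis" is operationalised as a
consecutive-trial sign change because no finer definition is standard.

## Force environments

All four fields are evaluated literally on the hand state (SI units):

* VDCF: `F = B1 [[0,−1],[1,0]] v` — always perpendicular to velocity.
* LIPF: `Fx = −K1 y`.
* PSPF: `Fx = −K2 (cos(π+40y)+1)/(π+40y)⁵` with y in metres and the
  argument in radians; with K2 = 20868 N/m this yields order-1 N forces,
  near zero at start and target and peaking in the first half of the
  reach.
* CPVF: the LIPF term minus the VDCF term, minus sign preserved as
  defined (it flips the curl direction relative to VDCF).

Experimental gains are B1 = 14 N·s/m, K1 = 60 N/m.  Simulations use the
weaker/stronger gains appropriate to each plant: B1 = 7, K1 = 120 for the
point-mass OFC plant; B1 = 20, K1 = 120 for the arm (CPVF simulations
reuse the same gains; none are printed for it).  The partial error clamp
is a 1-D spring–damper along x active for y > 75 mm; three constant sets
are exposed (experiment 800/45, OFC simulation 1500/100, VS simulation
2500/1000 N/m, N·s/m) and none is privileged.

## Optimal-feedback-control model

Plant: planar point mass (1 kg) with actuated force following the command
through a 60 ms first-order lag; semi-implicit Euler at Δt = 10 ms;
horizon T + T_hold = 450 ms.  The per-trial policy is a finite-horizon
time-varying LQR on the augmented state [p, v, f, 1] for the *believed*
dynamics, in which the external force is predicted as `α·D x` (for the
PSPF, which has no force matrix, as an α-scaled feedforward drift along
the nominal straight minimum-jerk path).  The rollout uses the true
field, clamp and lock; the controller sees the exact state (noise-free
certainty equivalence), so all behavioural error comes from the α-scaled
model mismatch.

Stage costs: endpoint terms (position error 4·10⁴, velocity 10², force
10⁻²) act at and after T; a control cost r·|u|² (r = 10⁻⁴) acts
throughout, as do small running costs on lateral position (100) and
lateral velocity (1).  The running lateral terms are required for the
fully adapted controller to *compensate* a known field rather than
exploit it — with endpoint-only costs the α = 1 policy rides the curl
field ~18 mm off the straight line at any effort price.  All magnitudes
were calibrated once so the null reach is straight, 150 mm, ends inside
the target on time, and were not revisited.

Internal-model schedule: α = 0.8·log(log i + 1)/log(log 155 + 1) over
adaptation (natural logarithms), and the decreasing mirror
0.8·[1 − log(log(i−155)+1)/log(log 30 + 1)] over the first 30 washout
trials, 0 thereafter.  (The source text describes the washout schedule as
decreasing while printing an increasing formula; the decreasing reading
is implemented.)

Hierarchical layer: the bias term
`w_bias · e^(−t/τ) (k_p pᵀQ_d p + k_v vᵀQ_d v)` with k_p = k_v = 0.5,
τ = 130 ms, and an overall scale w_bias = 3000 calibrated here (the
original cost units are not published; k_p, k_v are meaningful only
relative to that scale).  The term is added only once the layer has been
activated by a failure, which makes the flat and hierarchical variants
*exactly* identical on failure-free conditions (VDCF, PSPF) — a φ = 0
bias term would still penalise lateral motion.  After a failed trial
φ ← b·φ − r·θ with b = 0.95, r = 0.85 and θ the endpoint direction error
in degrees (clockwise positive); after successes φ ← b·φ.

Motor-cost gate: the trial cost Σ uᵀR u is mapped by a calibrated scale
(0.080) into the gate's units so that the printed threshold 0.01 sits
just above the nominal null-reach cost.  The gate is *state-dependent*:
on any trial whose cost is below threshold the forgetting rate is treated
as 1 (no decay), and decay resumes if cost rises above threshold again.
A permanently latched freeze was rejected: in the muscle-space model the
adaptation-phase cost passes through the same band as the washout tail,
and a latch acquired mid-adaptation lets washout failures wind the plan
up without any decay (runaway deflections of hundreds of mm).  The
state-dependent gate instead creates a stable attractor at the threshold
contour and produces the persistent ~4 mm curved null trajectory after
the failure-inducing field, while the clamp condition (no washout
failures, plan already near zero) returns to baseline.

## V-shaped learning model

Arm: two links (l = 0.30/0.33 m, m = 1.93/1.52 kg, standard inertias and
joint damping), shoulder at the origin, start at (0, 0.35) m, target at
(0, 0.50) m; six muscles (shoulder, elbow and bi-articular
flexor/extensor pairs) with constant moment arms and muscle length linear
in joint angles, so uniform co-activation produces no net torque.
Tension of muscle k at time t:

    T_k = [ u_k + c·u_k·(E_k + g_d Ė_k) + g_r·(E_k + g_d Ė_k)(t−δ) ]₊

with feedforward u, activation-proportional intrinsic visco-elasticity
(c = 35 m⁻¹ — co-contraction stiffens the arm, which is what makes the
trial-to-trial learning loop self-stabilising), and a delayed reflex
(g_r = 6000 N/m, δ = 60 ms, g_d = 0.08 s).  E is the muscle-length error
from the desired trajectory's muscle-space image.  Integration:
semi-implicit Euler at 2 ms with clamp/lock damping handled implicitly
(explicit treatment is unstable at the clamp's 1000 N·s/m).

Learning: `Δu = α_l[ε]₊ + β_l[−ε]₊ − γ_l` with α_l = 4000, β_l = 2000
N/m, γ_l = 1 N, read 60 ms ahead (the feedback delay) and smoothed with
an 80 ms boxcar before being added and rectified.  The smoothing is a
numerical necessity standing in for activation low-pass dynamics: with
pointwise updates the trial-domain map amplifies ~5–10 Hz error modes and
diverges after ~140 trials.  Gains were chosen for monotone convergence
of the tracking error on the nominal plant and a first-trial VDCF
response resembling the experiments (LD ≈ −19 mm, TE within the target).

The feedforward issued on each trial is the inverse-dynamics image of the
*current* desired trajectory (plus u_base = 450 N co-activation) plus the
learned correction; the V-shaped law updates the correction.  This makes
a change of plan effective immediately — with a fixed feedforward the
via-point deflection has no behavioural effect and winds up without
bound.  The desired trajectory is the straight minimum-jerk reach (flat
variant) or the minimum-jerk trajectory through the via-point
(dx, 120 mm), solved in closed form (quintic plus a (t−t₁)⁵₊ term) with
the passage time chosen to minimise integrated squared jerk, which
recovers the straight reach exactly at dx = 0.  Deflection update:
dx ← b·dx − r·TE (b = 0.95, r = 0.45, TE in metres) after failures,
dx ← b·dx after successes, same state-dependent cost gate as above with
motor cost = average muscle tension across the six muscles during the
movement.  The printed gate value (350) presumes the original model's
tension units; with this arm parameterisation the calibrated equivalent
is 445 N.

## Protocols

Every condition runs 50 baseline + 5 pre-null + 155 adaptation + 150
de-adaptation trials; simulations start at adaptation trial 1 (the
practised baseline is the initial condition: a converged straight reach).
LIPF_PEC applies the clamp in de-adaptation only.  Rest breaks are
annotations without simulated effect.  Epoch summaries use the six
windows 1, 3–5, 136–155 (adaptation) and 1, 3–5, 131–150
(de-adaptation), indexed 1..305 across the two simulated phases.

## Statistics

`t_one_sample_summary` implements t = (m − μ₀)/(s/√n) so printed
mean ± s.d. tables can be re-tested; raw-vector t-tests wrap scipy.  The
one-way repeated-measures ANOVA (pingouin underneath) reports F, the
Box/Greenhouse–Geisser ε̂ with corrected degrees of freedom ε̂(k−1),
ε̂(k−1)(n−1), the GG-corrected p and partial η².  Tukey post-hocs for the
repeated-measures context use the ANOVA's within-error term with the
studentized-range distribution (no installed library exposes this
combination).  Bonferroni caps p·m at 1.  One published statistic does
not reproduce from its own summary numbers (the combined-field first
de-adaptation trial: t(12) = 5.211 reported vs 2.93 recomputed from
26.0 ± 22.8, n = 13, which also mixes n = 13 with df = 12); it is noted
here and not used as a check.

## Synthetic data generator

The generator is phenomenological — a fixture factory, not a third
model.  Per participant and phase, TE follows `TE = drive + dx + noise`
with a constant phase drive (first-trial drive ~ N(112.6, 38.0) mm across
participants; de-adaptation drive = −40% of it) and the deflection
recursion `dx' = b·dx − r·TE + η` (b = 0.95, r = 0.45, equation noise η
with 1 mm s.d. by default, observation noise 4 mm).  LD mixes the
residual (drive + dx) and dx.  Within-trial paths are minimum-jerk in y
with a smooth lateral profile pinned to the trial's LD at mid-reach and
TE at the endpoint, plus a short stationary tail so the endpoint readout
is exact; durations are 400 ± 20 ms.  Pathological fixtures (sub-75 mm
reaches; an unstable participant with alternating ±40 mm late-washout LD
and a shifted last-20 mean) can be injected to exercise the exclusion
rules.  What the generator does *not* emulate: within-trial feedback
corrections, velocity-profile variability beyond minimum jerk, any
coupling between TE and movement duration, or the hierarchical gating
itself — so pipeline tests validate the metrics/statistics machinery, not
the behavioural theory.  `UpdateRuleModel` recovers (b, r) from observed
(TE, dx) series by least squares on the recursion and flags a
rank-deficient design (e.g. an all-zero TE series) as unidentifiable.

## Numerical choices and limitations

* Deterministic throughout the simulators (all noise zero); randomness
  only in the generator and calibration tests, always seeded.
* The endpoint readout can bifurcate between two nearby speed minima as
  the trajectory deforms smoothly across trials, producing an isolated
  step in the per-trial |TE| series (one such step occurs mid-adaptation
  in the hierarchical OFC failure-field run); epoch-level decay is
  unaffected.
* The rollout is truncated at the policy horizon (OFC) or 650 ms (VS);
  the locked period beyond the endpoint readout carries no information.
* Divergence guards flag trials whose hand leaves a 1 m workspace.
* The hierarchical layers' magnitudes (peak LD excursion, peak
  deflection) are sensitive to the unpublished cost/impedance scales and
  should be read qualitatively; the signatures tested (sign reversal,
  monotone TE decay, persistent vs abolished null-trajectory curvature)
  are robust across the parameter ranges explored.
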