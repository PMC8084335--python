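"""Experiment schedules: phase structure and condition registry.

Every named condition follows the same session layout: 50 baseline trials
and 5 pre-field null trials, then 155 adaptation trials in the condition's
force field and 150 de-adaptation trials (null field, except LIPF_PEC whose
de-adaptation runs inside the partial error clamp).  Rest breaks after
adaptation trials 50/100/150 are annotations only and have no simulated
effect.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fields import ChannelSpec, FieldKind, FieldSpec

CONDITIONS = ("VDCF", "LIPF_NULL", "LIPF_PEC", "PSPF", "CPVF")

N_BASELINE = 50
N_PRE_NULL = 5
N_ADAPT = 155
N_DEADAPT = 150

#: Field gains used in model simulations (weaker than the experimental
#: gains, chosen to produce comparable hand paths for a point-mass plant).
SIM_GAINS_OFC = {"b1": 7.0, "k1": 120.0, "k2": 20868.0}
#: The V-shaped arm model uses a stronger curl gain.
SIM_GAINS_VS = {"b1": 20.0, "k1": 120.0, "k2": 20868.0}

#: Partial-error-clamp constants: experimental apparatus and the two
#: simulation variants.  None is privileged; simulators pick their own.
PEC_EXPERIMENT = ChannelSpec(stiffness=800.0, damping=45.0)
PEC_OFC = ChannelSpec(stiffness=1500.0, damping=100.0)
PEC_VS = ChannelSpec(stiffness=2500.0, damping=1000.0)

REST_BREAK_AFTER = (50, 100, 150)  # adaptation trials; annotation only


@dataclass(frozen=True)
class Phase:
    label: str  # baseline | pre_null | adaptation | de_adaptation
    trial_count: int
    field: FieldSpec
    channel: ChannelSpec | None = None


@dataclass(frozen=True)
class Schedule:
    condition: str
    phases: tuple[Phase, ...]

    @property
    def n_trials(self) -> int:
        return sum(p.trial_count for p in self.phases)

    def counted_phases(self) -> tuple[Phase, ...]:
        """Adaptation + de-adaptation phases (the simulated schedule)."""
        return tuple(p for p in self.phases if p.label in ("adaptation", "de_adaptation"))


def _adapt_field(condition: str, gains: dict) -> FieldSpec:
    kind = {"VDCF": FieldKind.VDCF, "LIPF_NULL": FieldKind.LIPF,
            "LIPF_PEC": FieldKind.LIPF, "PSPF": FieldKind.PSPF,
            "CPVF": FieldKind.CPVF}[condition]
    return FieldSpec(kind=kind, **gains)


def make_schedule(
    condition: str,
    gains: dict | None = None,
    pec: ChannelSpec = PEC_EXPERIMENT,
) -> Schedule:
    """Build the full session schedule for one named condition.

    ``gains`` defaults to the experimental field gains; simulators pass
    their own.  LIPF_PEC applies the clamp in de-adaptation only.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    from .fields import EXPERIMENT_GAINS

    gains = dict(gains if gains is not None else EXPERIMENT_GAINS)
    null = FieldSpec(kind=FieldKind.NULL)
    deadapt_channel = pec if condition == "LIPF_PEC" else None
    phases = (
        Phase("baseline", N_BASELINE, null),
        Phase("pre_null", N_PRE_NULL, null),
        Phase("adaptation", N_ADAPT, _adapt_field(condition, gains)),
        Phase("de_adaptation", N_DEADAPT, null, channel=deadapt_channel),
    )
    return Schedule(condition=condition, phases=phases)
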