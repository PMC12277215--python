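"""Five-phase gait segmentation state machine and stride detection.

Each leg is, at every time step, in exactly one of Early Stance, Late
Stance, Lift Off, Swing, or Landing.  Transitions are driven by the
sagittal foot position (relative to the whole-body center of mass,
positive in the walking direction) and the normalized leg load (ground
reaction force magnitude over body weight):

* Landing -> Early Stance when the leg load exceeds the stance load
  threshold (touchdown);
* Early Stance -> Late Stance when the sagittal foot position falls below
  the Late Stance threshold;
* Late Stance -> Lift Off when the contralateral leg load exceeds the
  stance load threshold, or the sagittal position falls below the liftoff
  threshold;
* Lift Off -> Swing when the leg load falls below the Swing load
  threshold;
* Swing -> Landing when the sagittal foot position exceeds the landing
  threshold.

All comparisons are strict; at most one transition fires per time step.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GaitPhase",
    "CANONICAL_PHASE_ORDER",
    "PhaseThresholds",
    "LegState",
    "next_phase",
    "resolve_initial_phase",
    "label_phases",
    "detect_strides",
    "NoStrideError",
    "leg_states_to_frame",
    "leg_states_from_frame",
]


class GaitPhase(enum.Enum):
    """The five gait phases, in canonical cycle order."""

    EARLY_STANCE = "EarlyStance"
    LATE_STANCE = "LateStance"
    LIFT_OFF = "LiftOff"
    SWING = "Swing"
    LANDING = "Landing"

    @property
    def abbrev(self) -> str:
        return _ABBREV[self]

    def __repr__(self) -> str:  # compact in test output
        return f"<{self.value}>"


_ABBREV = {
    GaitPhase.EARLY_STANCE: "ES",
    GaitPhase.LATE_STANCE: "LS",
    GaitPhase.LIFT_OFF: "LO",
    GaitPhase.SWING: "SW",
    GaitPhase.LANDING: "LN",
}

#: Canonical ordering used for pattern bit masks and cycle checks.
CANONICAL_PHASE_ORDER = (
    GaitPhase.EARLY_STANCE,
    GaitPhase.LATE_STANCE,
    GaitPhase.LIFT_OFF,
    GaitPhase.SWING,
    GaitPhase.LANDING,
)

#: Legal successor of each phase in the gait cycle.
PHASE_SUCCESSOR = {
    GaitPhase.EARLY_STANCE: GaitPhase.LATE_STANCE,
    GaitPhase.LATE_STANCE: GaitPhase.LIFT_OFF,
    GaitPhase.LIFT_OFF: GaitPhase.SWING,
    GaitPhase.SWING: GaitPhase.LANDING,
    GaitPhase.LANDING: GaitPhase.EARLY_STANCE,
}


@dataclass(frozen=True)
class PhaseThresholds:
    """Threshold set driving the transition rules.

    Loads are body-weight fractions; sagittal thresholds are meters
    relative to the body center of mass.
    """

    stance_load_threshold: float = 0.2
    late_stance_sagittal_threshold: float = 0.0
    liftoff_sagittal_threshold: float = -0.35
    swing_load_threshold: float = 0.1
    landing_sagittal_threshold: float = 0.15

    def __post_init__(self) -> None:
        for name in ("stance_load_threshold", "swing_load_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 2.0:
                raise ValueError(f"{name} must be in [0, 2], got {v}")
        if self.swing_load_threshold > self.stance_load_threshold:
            raise ValueError(
                "swing_load_threshold must not exceed stance_load_threshold"
            )


@dataclass(frozen=True)
class LegState:
    """Instantaneous observables of one leg used by the phase machine."""

    sagittal_foot_position: float
    leg_load: float
    contralateral_leg_load: float = 0.0

    def __post_init__(self) -> None:
        if self.leg_load < 0 or self.contralateral_leg_load < 0:
            raise ValueError("leg loads must be >= 0")


def next_phase(current: GaitPhase, state: LegState, thr: PhaseThresholds) -> GaitPhase:
    """Apply the single applicable transition rule, or stay put.

    Exactly one rule is checked per phase, so at most one transition can
    fire per call.
    """
    if current is GaitPhase.LANDING:
        if state.leg_load > thr.stance_load_threshold:
            return GaitPhase.EARLY_STANCE
    elif current is GaitPhase.EARLY_STANCE:
        if state.sagittal_foot_position < thr.late_stance_sagittal_threshold:
            return GaitPhase.LATE_STANCE
    elif current is GaitPhase.LATE_STANCE:
        if (
            state.contralateral_leg_load > thr.stance_load_threshold
            or state.sagittal_foot_position < thr.liftoff_sagittal_threshold
        ):
            return GaitPhase.LIFT_OFF
    elif current is GaitPhase.LIFT_OFF:
        if state.leg_load < thr.swing_load_threshold:
            return GaitPhase.SWING
    elif current is GaitPhase.SWING:
        if state.sagittal_foot_position > thr.landing_sagittal_threshold:
            return GaitPhase.LANDING
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown phase {current!r}")
    return current


def resolve_initial_phase(state: LegState, thr: PhaseThresholds) -> GaitPhase:
    """Deterministic mid-cycle start: loaded leg -> Early Stance, else Swing."""
    if state.leg_load > thr.stance_load_threshold:
        return GaitPhase.EARLY_STANCE
    return GaitPhase.SWING


def label_phases(
    states: Sequence[LegState],
    thr: PhaseThresholds,
    initial: GaitPhase | None = None,
) -> list[GaitPhase]:
    """Label a leg-state time series by stepping the machine sample-by-sample."""
    if len(states) == 0:
        raise ValueError("states series must be nonempty")
    if initial is None:
        initial = resolve_initial_phase(states[0], thr)
    labels = [next_phase(initial, states[0], thr)]
    for state in states[1:]:
        labels.append(next_phase(labels[-1], state, thr))
    return labels


class NoStrideError(ValueError):
    """Raised when a series contains fewer than two touchdowns."""


def detect_strides(labels: Sequence[GaitPhase]) -> list[tuple[int, int]]:
    """Half-open stride intervals between Landing->EarlyStance touchdowns.

    A touchdown is any index ``t`` where ``labels[t]`` is Early Stance and
    ``labels[t-1]`` is not (index 0 counts if it starts in Early Stance
    immediately after an implicit landing -- it does not, by convention:
    strides need an observed transition).
    """
    touchdowns = [
        t
        for t in range(1, len(labels))
        if labels[t] is GaitPhase.EARLY_STANCE
        and labels[t - 1] is GaitPhase.LANDING
    ]
    if len(touchdowns) < 2:
        raise NoStrideError(
            f"need >= 2 touchdowns for a stride, found {len(touchdowns)}"
        )
    return [(a, b) for a, b in zip(touchdowns[:-1], touchdowns[1:])]


def leg_states_to_frame(
    t: np.ndarray,
    left: Sequence[LegState],
    right: Sequence[LegState],
    labels_left: Sequence[GaitPhase] | None = None,
    labels_right: Sequence[GaitPhase] | None = None,
) -> pd.DataFrame:
    """Tabulate bilateral leg states (and optional labels) for CSV export."""
    frame = pd.DataFrame(
        {
            "t": np.asarray(t, dtype=float),
            "sagittal_pos_L": [s.sagittal_foot_position for s in left],
            "sagittal_pos_R": [s.sagittal_foot_position for s in right],
            "load_L": [s.leg_load for s in left],
            "load_R": [s.leg_load for s in right],
        }
    )
    if labels_left is not None:
        frame["phase_L"] = [p.value for p in labels_left]
    if labels_right is not None:
        frame["phase_R"] = [p.value for p in labels_right]
    return frame


def leg_states_from_frame(frame: pd.DataFrame) -> tuple[list[LegState], list[LegState]]:
    left = [
        LegState(px, lx, lc)
        for px, lx, lc in zip(frame.sagittal_pos_L, frame.load_L, frame.load_R)
    ]
    right = [
        LegState(px, lx, lc)
        for px, lx, lc in zip(frame.sagittal_pos_R, frame.load_R, frame.load_L)
    ]
    return left, right
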