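"""Synthetic inputs: baseline gait presets, scripted leg-state traces, and
a known-optimum noisy design-cost surrogate.

Everything here is generated programmatically so the whole pipeline is
testable offline.  The gait presets were fitted once from canonical
sagittal joint-angle curves and verified to simulate a valid gait (legal
phase sequence, >= 3 strides in 10 s, speed on target, early-stance
negative knee power); the coefficients are frozen below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from damperopt.device import DesignParams, pattern_mask
from damperopt.gait_model import (
    Anthropometry,
    ControllerTheta,
    ScenarioConfig,
    default_anthropometry,
)
from damperopt.phases import (
    CANONICAL_PHASE_ORDER,
    GaitPhase,
    LegState,
    PHASE_SUCCESSOR,
    PhaseThresholds,
)

__all__ = [
    "SurrogateSpec",
    "default_surrogate",
    "surrogate_cost",
    "make_surrogate_evaluator",
    "ScriptEntry",
    "make_scripted_leg_trace",
    "full_cycle_script",
    "multi_cycle_script",
    "all_stance_script",
    "baseline_gait_preset",
    "baseline_theta_std",
]


# --------------------------------------------------------------------------
# design-cost surrogate with a known analytic optimum
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SurrogateSpec:
    """Noisy quadratic-bowl design cost with a unique known minimum.

    Noiseless cost is ``base_cost + curvature*(c - c_star)^2 +
    offset(pattern)`` where the per-pattern offset is strictly positive for
    every pattern except ``pattern_star``.  Designs inside the penalty
    region are reported at ``penalty_value`` (mimicking unstable
    simulations).
    """

    c_star: float = 2.0
    pattern_star: frozenset = frozenset(
        {GaitPhase.EARLY_STANCE, GaitPhase.LATE_STANCE}
    )
    curvature: float = 0.05
    offset_scale: float = 0.05
    noise_std: float = 0.01
    base_cost: float = 0.85
    penalty_value: float = 10.0
    penalty_c_above: float = np.inf  # designs with c above this are "unstable"
    c_min: float = 0.0
    c_max: float = 5.0

    def pattern_offset(self, pattern: frozenset) -> float:
        """Hamming distance to the optimal pattern, scaled; 0 only at p*."""
        diff = len(pattern.symmetric_difference(self.pattern_star))
        return self.offset_scale * diff

    def noiseless(self, design: DesignParams) -> float:
        if design.damping_coefficient > self.penalty_c_above:
            return self.penalty_value
        return (
            self.base_cost
            + self.curvature * (design.damping_coefficient - self.c_star) ** 2
            + self.pattern_offset(design.clutch_pattern)
        )

    def cost_range(self) -> float:
        """Range of the noiseless cost over the box (excluding penalties)."""
        worst_c = max(
            (self.c_min - self.c_star) ** 2, (self.c_max - self.c_star) ** 2
        )
        worst_offset = self.offset_scale * len(CANONICAL_PHASE_ORDER)
        return self.curvature * worst_c + worst_offset


def default_surrogate(noise_std: float = 0.01) -> SurrogateSpec:
    return SurrogateSpec(noise_std=noise_std)


def surrogate_cost(
    design: DesignParams, spec: SurrogateSpec, rng: np.random.Generator
) -> float:
    """One noisy draw of the surrogate cost (penalties are noise-free)."""
    value = spec.noiseless(design)
    if value >= spec.penalty_value:
        return value
    return value + rng.normal(0.0, spec.noise_std)


def make_surrogate_evaluator(spec: SurrogateSpec, seed: int):
    """Seeded evaluator ``design -> noisy cost`` for the outer optimizer."""
    rng = np.random.default_rng(seed)

    def evaluate(design: DesignParams) -> float:
        return surrogate_cost(design, spec, rng)

    return evaluate


# --------------------------------------------------------------------------
# scripted leg-state traces for the phase machine
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScriptEntry:
    """A block of identical leg states whose phase label is known."""

    phase: GaitPhase
    state: LegState
    n: int = 5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("entry length must be >= 1")


def make_scripted_leg_trace(
    entries: list[ScriptEntry],
) -> tuple[list[LegState], list[GaitPhase]]:
    """Expand a script into a state series and its expected labels.

    Consecutive entries must stay in the same phase or advance one step
    along the canonical cycle; anything else is inconsistent with the
    transition graph and raises.
    """
    if not entries:
        raise ValueError("script must be nonempty")
    for prev, cur in zip(entries[:-1], entries[1:]):
        if cur.phase is not prev.phase and cur.phase is not PHASE_SUCCESSOR[prev.phase]:
            raise ValueError(
                f"inconsistent script: {prev.phase} cannot be followed by {cur.phase}"
            )
    states: list[LegState] = []
    expected: list[GaitPhase] = []
    for entry in entries:
        states.extend([entry.state] * entry.n)
        expected.extend([entry.phase] * entry.n)
    return states, expected


def _cycle_entries(thr: PhaseThresholds, n: int) -> list[ScriptEntry]:
    """One ES->LS->LO->SW->LN pass, each rule fired exactly once."""
    hi = thr.stance_load_threshold + 0.3
    lo = thr.swing_load_threshold / 2.0
    front = thr.landing_sagittal_threshold + 0.15
    behind = thr.late_stance_sagittal_threshold - 0.05
    return [
        ScriptEntry(GaitPhase.EARLY_STANCE, LegState(front, hi, lo), n),
        ScriptEntry(GaitPhase.LATE_STANCE, LegState(behind, hi, lo), n),
        ScriptEntry(GaitPhase.LIFT_OFF, LegState(behind, hi, hi), n),
        ScriptEntry(GaitPhase.SWING, LegState(behind, lo, hi), n),
        ScriptEntry(GaitPhase.LANDING, LegState(front, lo, hi), n),
    ]


def full_cycle_script(
    thr: PhaseThresholds | None = None, n: int = 5
) -> tuple[list[LegState], list[GaitPhase], GaitPhase]:
    """Single full cycle starting from Landing; fires all five rules."""
    thr = thr or PhaseThresholds()
    states, expected = make_scripted_leg_trace(_cycle_entries(thr, n))
    return states, expected, GaitPhase.LANDING


def multi_cycle_script(
    cycles: int, thr: PhaseThresholds | None = None, n: int = 5
) -> tuple[list[LegState], list[GaitPhase], GaitPhase]:
    """``cycles`` consecutive gait cycles -> exactly ``cycles`` touchdowns.

    Ends on an Early Stance block so the final Landing -> Early Stance
    touchdown is observed, giving ``cycles`` touchdowns and
    ``cycles - 1`` complete strides.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    thr = thr or PhaseThresholds()
    entries: list[ScriptEntry] = []
    for _ in range(cycles):
        entries.extend(_cycle_entries(thr, n))
    entries.append(_cycle_entries(thr, n)[0])
    states, expected = make_scripted_leg_trace(entries)
    return states, expected, GaitPhase.LANDING


def all_stance_script(
    thr: PhaseThresholds | None = None, n: int = 20
) -> tuple[list[LegState], list[GaitPhase], GaitPhase]:
    """Constant loaded, forward-foot trace: stays in Early Stance."""
    thr = thr or PhaseThresholds()
    state = LegState(0.2, thr.stance_load_threshold + 0.5, 0.0)
    states, expected = make_scripted_leg_trace(
        [ScriptEntry(GaitPhase.EARLY_STANCE, state, n)]
    )
    return states, expected, GaitPhase.EARLY_STANCE


# --------------------------------------------------------------------------
# baseline gait presets (coefficients frozen from the one-off fit)
# --------------------------------------------------------------------------

_LEVEL_THETA = ControllerTheta(
    hip_coeffs=(0.23511, 0.34374, -0.10209, -0.05486, -0.01789, 0.00701, 0.00648),
    knee_coeffs=(0.40881, -0.03158, -0.37131, -0.26521, 0.10654, -0.01063, 0.07769),
    ankle_coeffs=(0.02422, -0.04521, 0.09413, 0.05228, -0.11596, -0.06923, 0.00249),
    stride_period=1.1,
    stride_length=1.32,
    pelvis_height=0.86,
    pelvis_vert_amp=0.012,
    pelvis_vert_phase=0.0,
    pelvis_fore_amp=0.008,
    pelvis_fore_phase=0.0,
    stance_load_threshold=0.2,
)

_DOWNHILL_THETA = ControllerTheta(
    hip_coeffs=(0.25366, 0.35719, -0.07613, -0.06295, -0.00772, 0.00888, 0.00384),
    knee_coeffs=(0.43947, 0.00936, -0.35671, -0.24454, 0.14145, -0.00333, 0.10878),
    ankle_coeffs=(0.02422, -0.04521, 0.09413, 0.05228, -0.11596, -0.06923, 0.00249),
    stride_period=1.1,
    stride_length=1.32,
    pelvis_height=0.85,
    pelvis_vert_amp=0.012,
    pelvis_vert_phase=0.0,
    pelvis_fore_amp=0.008,
    pelvis_fore_phase=0.0,
    stance_load_threshold=0.2,
)

_SCENARIOS = {
    "level": ScenarioConfig(slope_deg=0.0, name="level"),
    "downhill": ScenarioConfig(slope_deg=-5.0, name="downhill"),
}


def baseline_gait_preset(
    scenario: str,
) -> tuple[ControllerTheta, Anthropometry, ScenarioConfig]:
    """Packaged baseline gait for ``'level'`` or ``'downhill'``.

    Both presets simulate valid (speed on target, legal phase sequence,
    >= 3 strides in 10 s) with a negative-knee-power region in Early
    Stance; the downhill preset's is deeper.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected one of {sorted(_SCENARIOS)}"
        )
    theta = _LEVEL_THETA if scenario == "level" else _DOWNHILL_THETA
    return theta, default_anthropometry(), _SCENARIOS[scenario]


def baseline_theta_std(theta: ControllerTheta) -> np.ndarray:
    """Per-component search stds for warm-started inner optimization.

    Small by construction: the assisted gait is expected to stay close to
    the baseline solution.
    """
    n_coeffs = (
        len(theta.hip_coeffs) + len(theta.knee_coeffs) + len(theta.ankle_coeffs)
    )
    std = np.full(n_coeffs + len(ControllerTheta._SCALARS), 0.01)
    scalar_std = {
        "stride_period": 0.01,
        "stride_length": 0.02,
        "pelvis_height": 0.005,
        "pelvis_vert_amp": 0.002,
        "pelvis_vert_phase": 0.05,
        "pelvis_fore_amp": 0.002,
        "pelvis_fore_phase": 0.05,
        "stance_load_threshold": 0.02,
    }
    for i, name in enumerate(ControllerTheta._SCALARS):
        std[n_coeffs + i] = scalar_std[name]
    return std
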