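"""Damper-clutch device model and the design space it induces.

The device is a linear rotational damper at the knee that a clutch engages
only during a selected subset of the five gait phases.  A design is fully
described by the damping coefficient ``c`` (N*m*s/rad) and that subset
(the *clutch pattern*).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from damperopt.phases import CANONICAL_PHASE_ORDER, GaitPhase

__all__ = [
    "DesignParams",
    "DesignSpace",
    "damper_torque",
    "enumerate_clutch_patterns",
    "build_design_grid",
    "pattern_mask",
    "pattern_from_mask",
    "derive_c_max",
    "grid_to_frame",
    "grid_from_frame",
]


@dataclass(frozen=True)
class DesignParams:
    """One point of the device design space.

    Parameters
    ----------
    damping_coefficient : float
        Linear damping coefficient ``c`` in N*m*s/rad.  Must be >= 0.
    clutch_pattern : frozenset of GaitPhase
        Nonempty set of phases during which the damper is engaged.  The
        empty pattern is the no-device baseline and is not part of the
        design space.
    """

    damping_coefficient: float
    clutch_pattern: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not np.isfinite(self.damping_coefficient) or self.damping_coefficient < 0:
            raise ValueError(
                f"damping_coefficient must be finite and >= 0, "
                f"got {self.damping_coefficient!r}"
            )
        pattern = frozenset(self.clutch_pattern)
        if not pattern:
            raise ValueError("clutch_pattern must be a nonempty set of gait phases")
        if not pattern <= set(GaitPhase):
            raise ValueError(f"unknown phases in clutch_pattern: {pattern}")
        object.__setattr__(self, "clutch_pattern", pattern)

    @property
    def mask(self) -> int:
        return pattern_mask(self.clutch_pattern)

    def engaged(self, phase: GaitPhase) -> bool:
        return phase in self.clutch_pattern

    def label(self) -> str:
        """Short human-readable pattern label, e.g. ``'ES+LS'``."""
        return "+".join(p.abbrev for p in CANONICAL_PHASE_ORDER if p in self.clutch_pattern)


@dataclass(frozen=True)
class DesignSpace:
    """Bounds and discretization of the design space.

    ``c_grid`` spans ``[c_min, c_max]`` with ``n_grid`` evenly spaced
    values inclusive of both endpoints; ``patterns`` defaults to all 31
    nonempty subsets of the five phases.
    """

    c_min: float = 0.0
    c_max: float = 5.0
    n_grid: int = 41
    patterns: tuple = ()

    def __post_init__(self) -> None:
        if self.n_grid < 1:
            raise ValueError(f"n_grid must be >= 1, got {self.n_grid}")
        if self.c_max <= self.c_min:
            raise ValueError(
                f"c_max must exceed c_min, got [{self.c_min}, {self.c_max}]"
            )
        if self.c_min < 0:
            raise ValueError("c_min must be >= 0")
        patterns = tuple(self.patterns) or tuple(
            enumerate_clutch_patterns(CANONICAL_PHASE_ORDER)
        )
        object.__setattr__(self, "patterns", patterns)

    @property
    def c_grid(self) -> np.ndarray:
        return np.linspace(self.c_min, self.c_max, self.n_grid)

    @property
    def c_range(self) -> float:
        return self.c_max - self.c_min

    def __len__(self) -> int:
        return self.n_grid * len(self.patterns)


def damper_torque(c: float, omega_knee, engaged) -> float | np.ndarray:
    """Resistive torque of the linear damper: ``-c * omega`` when engaged.

    The clutch applies exactly zero torque while disengaged.  Accepts
    scalars or aligned arrays for ``omega_knee``/``engaged``.

    Raises
    ------
    ValueError
        If ``c`` is negative or non-finite.
    """
    if not np.isfinite(c) or c < 0:
        raise ValueError(f"damping coefficient must be finite and >= 0, got {c!r}")
    omega = np.asarray(omega_knee, dtype=float)
    eng = np.asarray(engaged, dtype=bool)
    tau = np.where(eng, -c * omega, 0.0)
    if np.ndim(omega_knee) == 0 and np.ndim(engaged) == 0:
        return float(tau)
    return tau


def enumerate_clutch_patterns(phases: Sequence[GaitPhase]) -> list[frozenset]:
    """All nonempty subsets of ``phases``, ordered by binary mask.

    Bit ``i`` of the mask corresponds to ``phases[i]`` (canonical order
    ES, LS, LO, SW, LN), so five phases yield the 31 admissible patterns.
    """
    phases = list(phases)
    if not phases:
        raise ValueError("phases must be nonempty")
    if len(set(phases)) != len(phases):
        raise ValueError(f"duplicate phase identifiers: {phases}")
    out = []
    for mask in range(1, 2 ** len(phases)):
        out.append(frozenset(p for i, p in enumerate(phases) if mask >> i & 1))
    return out


def pattern_mask(pattern: Iterable[GaitPhase]) -> int:
    """5-bit integer encoding of a pattern over the canonical phase order."""
    mask = 0
    for phase in pattern:
        mask |= 1 << CANONICAL_PHASE_ORDER.index(phase)
    return mask


def pattern_from_mask(mask: int) -> frozenset:
    if not 1 <= mask < 2 ** len(CANONICAL_PHASE_ORDER):
        raise ValueError(f"mask must be in [1, 31], got {mask}")
    return frozenset(
        p for i, p in enumerate(CANONICAL_PHASE_ORDER) if mask >> i & 1
    )


def build_design_grid(space: DesignSpace) -> list[DesignParams]:
    """Full-factorial grid: every damping value crossed with every pattern.

    41 damping values and all 31 patterns give the 1271-design validation
    grid.  Ordering is damping-major, pattern mask-minor.
    """
    return [
        DesignParams(damping_coefficient=float(c), clutch_pattern=pattern)
        for c in space.c_grid
        for pattern in space.patterns
    ]


def derive_c_max(peak_knee_moment: float, peak_knee_omega: float) -> float:
    """Upper damping bound as peak |knee moment| / peak |knee velocity|.

    Mirrors bounding the damper so its torque cannot exceed the largest
    moment the joint produces in a baseline run.
    """
    if peak_knee_omega <= 0:
        raise ValueError("peak knee angular velocity must be > 0")
    return abs(peak_knee_moment) / abs(peak_knee_omega)


def grid_to_frame(designs: Sequence[DesignParams]) -> pd.DataFrame:
    """Serialize a design list as columns ``c, pattern_mask, pattern_names``."""
    return pd.DataFrame(
        {
            "c": [d.damping_coefficient for d in designs],
            "pattern_mask": [d.mask for d in designs],
            "pattern_names": [d.label() for d in designs],
        }
    )


def grid_from_frame(frame: pd.DataFrame) -> list[DesignParams]:
    return [
        DesignParams(float(row.c), pattern_from_mask(int(row.pattern_mask)))
        for row in frame.itertuples()
    ]
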