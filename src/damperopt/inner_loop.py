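"""Inner loop: movement-cost evaluation and CMA-ES controller optimization.

The movement cost has four parts: a squared speed-tracking penalty, a
mass-specific effort term from the metabolic proxy, squared-excess
penalties on ankle excursion and normalized knee force, and a mean-excess
penalty on normalized GRF above a threshold.  CMA-ES is warm-started at
the baseline solution with small per-coordinate standard deviations, so
the adapted gait stays near the baseline gait by construction.

The CMA-ES implementation below is a minimal, deterministic
(rank-mu + rank-one, cumulative step-size adaptation) variant; it exists
in-package because the evaluation environment carries no dedicated
evolution-strategy library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from damperopt.gait_model import ControllerTheta, SimResult

__all__ = [
    "InnerCostConfig",
    "CostBreakdown",
    "inner_cost",
    "CMAES",
    "default_popsize",
    "InnerTrace",
    "optimize_controller",
]


# --------------------------------------------------------------------------
# movement cost
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class InnerCostConfig:
    """Weights, targets, and limits of the movement cost terms."""

    velocity_weight: float = 100.0
    velocity_target: float = 1.2
    effort_weight: float = 1.0
    ankle_weight: float = 10.0
    ankle_limits: tuple = (-1.0, 1.0)  # rad
    knee_force_weight: float = 10.0
    knee_force_limit: float = 8.0  # body-weight fractions
    grf_weight: float = 10.0
    grf_threshold: float = 1.4  # body-weight fractions

    def __post_init__(self) -> None:
        weights = (
            self.velocity_weight,
            self.effort_weight,
            self.ankle_weight,
            self.knee_force_weight,
            self.grf_weight,
        )
        if any(w < 0 for w in weights):
            raise ValueError("all weights must be >= 0")
        if not any(w > 0 for w in weights):
            raise ValueError("at least one weight must be > 0")


@dataclass(frozen=True)
class CostBreakdown:
    """Per-term values of the movement cost; total is their sum."""

    terms: dict

    @property
    def total(self) -> float:
        return float(sum(self.terms.values()))

    def __getitem__(self, key: str) -> float:
        return self.terms[key]


def _mean_sq_excess(x: np.ndarray, lo: float, hi: float) -> float:
    excess = np.maximum(x - hi, 0.0) + np.maximum(lo - x, 0.0)
    return float(np.mean(excess**2))


def inner_cost(result: SimResult, cfg: InnerCostConfig) -> CostBreakdown:
    """Evaluate the four-term movement cost on a simulation result.

    Raises
    ------
    ValueError
        If the result contains no complete stride on either leg.
    """
    if not (result.strides["right"] or result.strides["left"]):
        raise ValueError("movement cost needs at least one complete stride")

    duration = len(result.t) * result.dt
    velocity = cfg.velocity_weight * (result.mean_speed - cfg.velocity_target) ** 2
    effort = cfg.effort_weight * result.metabolic_energy / duration / result.total_mass

    lo, hi = cfg.ankle_limits
    ankle = cfg.ankle_weight * float(
        np.mean(
            [_mean_sq_excess(result.angles[leg]["ankle"], lo, hi) for leg in ("right", "left")]
        )
    )
    knee_force = cfg.knee_force_weight * float(
        np.mean(
            [
                _mean_sq_excess(
                    result.knee_force[leg] / result.body_weight,
                    -np.inf,
                    cfg.knee_force_limit,
                )
                for leg in ("right", "left")
            ]
        )
    )
    grf = cfg.grf_weight * float(
        np.mean(
            [
                np.mean(np.maximum(result.leg_load[leg] - cfg.grf_threshold, 0.0))
                for leg in ("right", "left")
            ]
        )
    )
    return CostBreakdown(
        terms={
            "velocity": velocity,
            "effort": effort,
            "ankle": ankle,
            "knee_force": knee_force,
            "grf": grf,
        }
    )


# --------------------------------------------------------------------------
# CMA-ES
# --------------------------------------------------------------------------


def default_popsize(dim: int) -> int:
    return 4 + int(3 * np.log(dim))


class CMAES:
    """Minimal covariance-matrix-adaptation evolution strategy (minimizer).

    Standard weighted-recombination parameters; ask/tell interface.  All
    randomness flows through one seeded generator, so identical seeds give
    bitwise-identical runs.
    """

    def __init__(
        self,
        x0: np.ndarray,
        sigma0: float,
        seed: int | None = None,
        popsize: int | None = None,
    ):
        self.mean = np.asarray(x0, dtype=float).copy()
        self.sigma = float(sigma0)
        self.n = self.mean.size
        self.rng = np.random.default_rng(seed)
        self.lam = popsize or default_popsize(self.n)
        self.mu = self.lam // 2

        w = np.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mueff = 1.0 / np.sum(self.weights**2)

        n, mueff = self.n, self.mueff
        self.cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
        self.cs = (mueff + 2) / (n + mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + mueff)
        self.cmu = min(
            1 - self.c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff)
        )
        self.damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + self.cs
        self.chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

        self.sigma_max = np.inf
        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self._decompose()
        self.generation = 0

    def _decompose(self) -> None:
        self.C = (self.C + self.C.T) / 2.0
        eigvals, eigvecs = np.linalg.eigh(self.C)
        eigvals = np.maximum(eigvals, 1e-20)
        self.B = eigvecs
        self.D = np.sqrt(eigvals)
        self.inv_sqrt_C = eigvecs @ np.diag(1.0 / self.D) @ eigvecs.T

    def ask(self) -> np.ndarray:
        self._z = self.rng.standard_normal((self.lam, self.n))
        self._y = self._z @ np.diag(self.D) @ self.B.T
        return self.mean + self.sigma * self._y

    def tell(self, solutions: np.ndarray, fitnesses: np.ndarray) -> None:
        order = np.argsort(fitnesses, kind="stable")
        y_sel = (solutions[order[: self.mu]] - self.mean) / self.sigma
        y_w = self.weights @ y_sel
        self.mean = self.mean + self.sigma * y_w

        self.ps = (1 - self.cs) * self.ps + np.sqrt(
            self.cs * (2 - self.cs) * self.mueff
        ) * (self.inv_sqrt_C @ y_w)
        hsig = float(
            np.linalg.norm(self.ps)
            / np.sqrt(1 - (1 - self.cs) ** (2 * (self.generation + 1)))
            / self.chi_n
            < 1.4 + 2 / (self.n + 1)
        )
        self.pc = (1 - self.cc) * self.pc + hsig * np.sqrt(
            self.cc * (2 - self.cc) * self.mueff
        ) * y_w

        rank_mu = sum(
            wk * np.outer(yk, yk) for wk, yk in zip(self.weights, y_sel)
        )
        self.C = (
            (1 - self.c1 - self.cmu) * self.C
            + self.c1
            * (
                np.outer(self.pc, self.pc)
                + (1 - hsig) * self.cc * (2 - self.cc) * self.C
            )
            + self.cmu * rank_mu
        )
        self.sigma *= np.exp(
            (self.cs / self.damps) * (np.linalg.norm(self.ps) / self.chi_n - 1)
        )
        self.sigma = float(min(self.sigma, self.sigma_max))
        self.generation += 1
        self._decompose()


# --------------------------------------------------------------------------
# controller optimization
# --------------------------------------------------------------------------


@dataclass
class InnerTrace:
    """Per-evaluation record of one inner optimization run."""

    evals: list = field(default_factory=list)  # (index, cost, valid)
    best_costs: list = field(default_factory=list)

    def record(self, cost: float) -> None:
        valid = bool(np.isfinite(cost))
        best = self.best_costs[-1] if self.best_costs else np.inf
        self.evals.append((len(self.evals), float(cost), valid))
        self.best_costs.append(min(best, cost if valid else np.inf))

    def __len__(self) -> int:
        return len(self.evals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.evals, columns=["eval", "cost", "valid"]).assign(
            best_cost=self.best_costs
        )


@dataclass
class InnerResult:
    theta_best: object  # same type as the warm start (vector or theta)
    cost_best: float
    trace: InnerTrace
    success: bool
    n_evals: int
    # final search-distribution mean/std in parameter units, usable as the
    # warm start of a subsequent constrained optimization
    final_mean: np.ndarray | None = None
    final_std: np.ndarray | None = None


def optimize_controller(
    evaluator: Callable,
    theta_mean,
    theta_std,
    budget: int,
    seed: int | None = None,
    popsize: int | None = None,
    max_deviation: float | None = 3.0,
    sigma_max: float = 2.0,
    bounds: tuple | None = None,
) -> InnerResult:
    """Warm-started CMA-ES over the controller parameterization.

    ``theta_mean`` may be a flat vector or a :class:`ControllerTheta`; the
    evaluator receives candidates of the same type and returns a scalar
    cost (non-finite or raised errors mark the candidate invalid).
    Candidates are sampled as ``mean + std * z`` with ``z`` from a unit
    CMA-ES, so the per-coordinate stds bound the deviation from the
    baseline; as they shrink to zero the search collapses onto the warm
    start.  ``max_deviation`` projects candidates onto the box
    ``mean +- max_deviation * std`` (the hard constraint keeping adapted
    gaits near the baseline solution); pass ``None`` for an unconstrained
    search.  ``bounds`` optionally adds an absolute ``(lo, hi)`` box in
    parameter units -- shared across warm starts, it pins successive
    optimizations to one region instead of letting each re-center the
    search.  At most ``budget`` evaluations are spent.
    """
    is_theta = isinstance(theta_mean, ControllerTheta)
    mean_vec = theta_mean.to_vector() if is_theta else np.asarray(theta_mean, float)
    std_vec = np.broadcast_to(np.asarray(theta_std, float), mean_vec.shape).copy()
    if np.any(std_vec <= 0):
        raise ValueError("theta_std must be elementwise > 0")

    es = CMAES(np.zeros(mean_vec.size), 1.0, seed=seed, popsize=popsize)
    es.sigma_max = sigma_max
    if budget < es.lam:
        raise ValueError(f"budget must cover one generation ({es.lam} evaluations)")

    if bounds is not None:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
        if np.any(lo > hi):
            raise ValueError("bounds must satisfy lo <= hi elementwise")

    def project(z: np.ndarray) -> np.ndarray:
        if max_deviation is not None:
            z = np.clip(z, -max_deviation, max_deviation)
        if bounds is not None:
            vec = np.clip(mean_vec + std_vec * z, lo, hi)
            z = (vec - mean_vec) / std_vec
        return z

    def to_candidate(z: np.ndarray):
        vec = mean_vec + std_vec * z
        return theta_mean.from_vector(vec) if is_theta else vec

    trace = InnerTrace()
    best_z = np.zeros(mean_vec.size)
    best_cost = np.inf
    n_evals = 0
    while n_evals + es.lam <= budget:
        zs = np.array([project(z) for z in es.ask()])
        costs = np.empty(es.lam)
        for i, z in enumerate(zs):
            try:
                c = float(evaluator(to_candidate(z)))
            except (ValueError, FloatingPointError):
                c = np.inf
            if not np.isfinite(c):
                c = np.inf
            costs[i] = c
            trace.record(c)
            if c < best_cost:
                best_cost = c
                best_z = z.copy()
            n_evals += 1
        es.tell(zs, costs)

    return InnerResult(
        theta_best=to_candidate(best_z),
        cost_best=float(best_cost),
        trace=trace,
        success=bool(np.isfinite(best_cost)),
        n_evals=n_evals,
        final_mean=mean_vec + std_vec * es.mean,
        final_std=es.sigma * np.sqrt(np.diag(es.C)) * std_vec,
    )
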