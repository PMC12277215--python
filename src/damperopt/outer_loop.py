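"""Outer loop: design cost, Bayesian design optimization, and validation.

The design cost is a weighted sum of the top-percentile knee-load
statistic and the cost of transport, each normalized by its baseline
(no-device) value; invalid simulations receive a fixed high penalty.  The
Bayesian optimizer models the cost with a Gaussian process (Matern
kernel + fitted white noise) over the damping coefficient and the 5-bit
clutch-pattern membership vector, proposing exact patterns (the
categorical dimension is never relaxed).  Each iteration draws its
acquisition function at random from {LCB, EI, PI}.  Brute-force grid
evaluation and multi-seed restarts mirror the validation protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from damperopt.device import DesignParams, DesignSpace, build_design_grid
from damperopt.gait_model import (
    Anthropometry,
    ControllerTheta,
    ScenarioConfig,
    SimResult,
    simulate,
)
from damperopt.inner_loop import InnerCostConfig, InnerResult, inner_cost, optimize_controller
from damperopt.phases import CANONICAL_PHASE_ORDER

__all__ = [
    "OuterCostConfig",
    "ProtocolConfig",
    "OptimizationTrace",
    "knee_load_statistic",
    "sim_knee_load_statistic",
    "cost_of_transport",
    "outer_cost",
    "BaselineContext",
    "make_baseline_context",
    "DesignEvaluation",
    "evaluate_design",
    "bayes_optimize",
    "brute_force",
    "run_restarts",
    "RestartResult",
    "RestartSummary",
    "summarize_restarts",
]

ACQUISITIONS = ("lcb", "ei", "pi")


# --------------------------------------------------------------------------
# design cost
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class OuterCostConfig:
    """Weights and baselines of the design cost."""

    knee_load_weight: float = 0.5
    cot_weight: float = 0.5
    top_percent: float = 10.0
    penalty: float = 10.0
    baseline_knee_load: float | None = None
    baseline_cot: float | None = None

    def __post_init__(self) -> None:
        if self.knee_load_weight < 0 or self.cot_weight < 0:
            raise ValueError("weights must be >= 0")
        if self.knee_load_weight + self.cot_weight <= 0:
            raise ValueError("at least one weight must be > 0")
        if not 0 < self.top_percent <= 100:
            raise ValueError("top_percent must be in (0, 100]")


def knee_load_statistic(
    load: np.ndarray, strides: Sequence[tuple[int, int]], q: float
) -> float:
    """Mean of the top-q% load samples per stride, averaged over strides."""
    if not 0 < q <= 100:
        raise ValueError("q must be in (0, 100]")
    if len(strides) == 0:
        raise ValueError("no strides to evaluate")
    load = np.asarray(load, dtype=float)
    per_stride = []
    for i0, i1 in strides:
        seg = np.sort(load[i0:i1])[::-1]
        k = int(np.ceil(q / 100.0 * len(seg)))
        per_stride.append(seg[:k].mean())
    return float(np.mean(per_stride))


def sim_knee_load_statistic(result: SimResult, q: float = 10.0) -> float:
    """Top-q% knee-load statistic, unweighted over strides of both legs."""
    per_stride = []
    for leg in ("right", "left"):
        for i0, i1 in result.strides[leg]:
            seg = np.sort(result.knee_load[leg][i0:i1])[::-1]
            k = int(np.ceil(q / 100.0 * len(seg)))
            per_stride.append(seg[:k].mean())
    if not per_stride:
        raise ValueError("no strides to evaluate")
    return float(np.mean(per_stride))


def cost_of_transport(metabolic_energy: float, distance: float) -> float:
    """Metabolic energy per distance traveled, J/m."""
    if distance <= 0:
        raise ValueError("distance must be > 0")
    return metabolic_energy / distance


def outer_cost(
    knee_load_stat: float,
    cot: float,
    cfg: OuterCostConfig,
    valid: bool = True,
) -> float:
    """Baseline-normalized weighted design cost; penalty when invalid."""
    if not valid:
        return cfg.penalty
    if cfg.baseline_knee_load is None or cfg.baseline_cot is None:
        raise ValueError("baseline metrics are not configured")
    if cfg.baseline_knee_load <= 0 or cfg.baseline_cot <= 0:
        raise ValueError("baseline metrics must be positive")
    return (
        cfg.knee_load_weight * knee_load_stat / cfg.baseline_knee_load
        + cfg.cot_weight * cot / cfg.baseline_cot
    )


# --------------------------------------------------------------------------
# design evaluation on the gait model
# --------------------------------------------------------------------------


@dataclass
class BaselineContext:
    """Everything a design evaluation needs besides the design itself."""

    theta: ControllerTheta
    theta_std: np.ndarray
    anthro: Anthropometry
    scenario: ScenarioConfig
    inner_cfg: InnerCostConfig
    outer_cfg: OuterCostConfig
    baseline_result: SimResult
    inner_budget: int = 150
    # absolute controller-parameter box shared by baseline and assisted
    # optimizations, anchoring adaptation to one neighborhood of gaits
    bounds: tuple | None = None


def make_baseline_context(
    scenario: str,
    inner_budget: int = 150,
    baseline_budget: int = 400,
    baseline_seed: int = 0,
    outer_cfg: OuterCostConfig | None = None,
) -> BaselineContext:
    """Optimize the no-device baseline gait and derive the cost baselines.

    The packaged preset seeds a device-free inner optimization; the
    optimized gait defines the baseline knee-load statistic and cost of
    transport, and its final CMA-ES mean and per-coordinate stds become
    the warm start of every assisted optimization (keeping assisted gaits
    close to the baseline solution).
    """
    from damperopt.fixtures import baseline_gait_preset, baseline_theta_std

    theta0, anthro, scen = baseline_gait_preset(scenario)
    inner_cfg = InnerCostConfig(velocity_target=scen.target_speed)
    std0 = baseline_theta_std(theta0)
    vec0 = theta0.to_vector()
    bounds = (vec0 - 3.0 * std0, vec0 + 3.0 * std0)

    def theta_evaluator(theta: ControllerTheta) -> float:
        res = simulate(None, theta, scen, anthro)
        if not res.valid:
            return np.inf
        return inner_cost(res, inner_cfg).total

    base_opt = optimize_controller(
        theta_evaluator,
        theta0,
        std0,
        budget=baseline_budget,
        seed=baseline_seed,
        bounds=bounds,
    )
    if not base_opt.success:
        raise RuntimeError("baseline optimization found no valid gait")
    theta = base_opt.theta_best
    result = simulate(None, theta, scen, anthro)
    if not result.valid:
        raise RuntimeError(f"optimized baseline is invalid: {result.invalid_reasons}")

    outer_cfg = outer_cfg or OuterCostConfig()
    outer_cfg = replace(
        outer_cfg,
        baseline_knee_load=sim_knee_load_statistic(result, outer_cfg.top_percent),
        baseline_cot=result.cost_of_transport,
    )
    theta_std = np.clip(base_opt.final_std, 1e-4, None)
    return BaselineContext(
        theta=theta,
        theta_std=theta_std,
        anthro=anthro,
        scenario=scen,
        inner_cfg=inner_cfg,
        outer_cfg=outer_cfg,
        baseline_result=result,
        inner_budget=inner_budget,
        bounds=bounds,
    )


@dataclass
class DesignEvaluation:
    design: DesignParams
    cost: float
    result: SimResult | None
    inner: InnerResult | None
    failed: bool = False


def evaluate_design(
    design: DesignParams,
    ctx: BaselineContext,
    seed: int | None = None,
) -> DesignEvaluation:
    """Inner-optimize the controller for one design and score the design.

    The controller is warm-started at the baseline theta; the returned
    cost is the baseline-normalized design cost of the best adapted gait
    (or the penalty if nothing valid was found).
    """

    def theta_evaluator(theta: ControllerTheta) -> float:
        res = simulate(design, theta, ctx.scenario, ctx.anthro)
        if not res.valid:
            return np.inf
        return inner_cost(res, ctx.inner_cfg).total

    inner = optimize_controller(
        theta_evaluator,
        ctx.theta,
        ctx.theta_std,
        budget=ctx.inner_budget,
        seed=seed,
        bounds=ctx.bounds,
    )
    if not inner.success:
        return DesignEvaluation(design, ctx.outer_cfg.penalty, None, inner, failed=True)

    result = simulate(design, inner.theta_best, ctx.scenario, ctx.anthro)
    if not result.valid:
        return DesignEvaluation(design, ctx.outer_cfg.penalty, result, inner, failed=True)
    cost = outer_cost(
        sim_knee_load_statistic(result, ctx.outer_cfg.top_percent),
        result.cost_of_transport,
        ctx.outer_cfg,
        valid=True,
    )
    return DesignEvaluation(design, cost, result, inner)


# --------------------------------------------------------------------------
# Bayesian optimization
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtocolConfig:
    """Outer-loop protocol: random warmup, convergence rule, restarts."""

    n_initial: int = 10
    window: int = 15
    epsilon: float = 1e-3
    max_iterations: int = 100
    n_restarts: int = 5
    failure_cost: float = 10.0

    def __post_init__(self) -> None:
        if self.n_initial < 1 or self.window < 1:
            raise ValueError("n_initial and window must be >= 1")
        if self.max_iterations < self.n_initial + self.window:
            raise ValueError("max_iterations must be >= n_initial + window")


@dataclass
class OptimizationTrace:
    """Per-iteration record of one outer optimization run."""

    seed: int | None
    designs: list = field(default_factory=list)
    costs: list = field(default_factory=list)
    best_costs: list = field(default_factory=list)
    acquisitions: list = field(default_factory=list)
    termination: str = ""

    def record(self, design: DesignParams, cost: float, acquisition: str) -> None:
        best = self.best_costs[-1] if self.best_costs else np.inf
        self.designs.append(design)
        self.costs.append(float(cost))
        self.best_costs.append(min(best, float(cost)))
        self.acquisitions.append(acquisition)

    def __len__(self) -> int:
        return len(self.costs)

    @property
    def best_cost(self) -> float:
        return self.best_costs[-1]

    @property
    def best_design(self) -> DesignParams:
        return self.designs[int(np.argmin(self.costs))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.costs)),
                "c": [d.damping_coefficient for d in self.designs],
                "pattern_mask": [d.mask for d in self.designs],
                "pattern_names": [d.label() for d in self.designs],
                "cost": self.costs,
                "best_cost": self.best_costs,
                "acquisition": self.acquisitions,
            }
        )


def _encode(designs: Sequence[DesignParams], space: DesignSpace) -> np.ndarray:
    rows = np.empty((len(designs), 1 + len(CANONICAL_PHASE_ORDER)))
    for i, d in enumerate(designs):
        rows[i, 0] = (d.damping_coefficient - space.c_min) / space.c_range
        for j, phase in enumerate(CANONICAL_PHASE_ORDER):
            rows[i, 1 + j] = 1.0 if phase in d.clutch_pattern else 0.0
    return rows


def _candidate_pool(
    space: DesignSpace, rng: np.random.Generator, n_extra_c: int = 24
) -> list[DesignParams]:
    cs = np.concatenate(
        [space.c_grid, rng.uniform(space.c_min, space.c_max, size=n_extra_c)]
    )
    return [
        DesignParams(float(c), pattern) for c in cs for pattern in space.patterns
    ]


def _acquisition_scores(
    name: str, mu: np.ndarray, sd: np.ndarray, y_best: float, kappa: float = 3.0
) -> np.ndarray:
    """Higher is better, for minimization of the objective."""
    sd = np.maximum(sd, 1e-12)
    if name == "lcb":
        return -(mu - kappa * sd)
    gain = (y_best - mu) / sd
    if name == "pi":
        return stats.norm.cdf(gain)
    if name == "ei":
        return (y_best - mu) * stats.norm.cdf(gain) + sd * stats.norm.pdf(gain)
    raise ValueError(f"unknown acquisition {name!r}")


def _is_near_duplicate(
    design: DesignParams,
    evaluated: Sequence[DesignParams],
    space: DesignSpace,
    tol: float = 1e-3,
) -> bool:
    return any(
        design.clutch_pattern == d.clutch_pattern
        and abs(design.damping_coefficient - d.damping_coefficient)
        < tol * space.c_range
        for d in evaluated
    )


def bayes_optimize(
    space: DesignSpace,
    evaluator: Callable[[DesignParams], float],
    protocol: ProtocolConfig | None = None,
    seed: int | None = None,
) -> OptimizationTrace:
    """GP-guided design search with probabilistic acquisition choice.

    Starts with ``n_initial`` seeded-random evaluations, then proposes the
    acquisition argmax over a candidate pool containing every clutch
    pattern (exact, never relaxed) crossed with gridded plus random
    damping values.  Stops when the best cost improved by less than
    ``epsilon`` over the trailing ``window`` evaluations, or at
    ``max_iterations``.
    """
    protocol = protocol or ProtocolConfig()
    rng = np.random.default_rng(seed)
    trace = OptimizationTrace(seed=seed)

    def run_one(design: DesignParams, acq: str) -> None:
        try:
            cost = float(evaluator(design))
        except Exception:
            cost = protocol.failure_cost
        if not np.isfinite(cost):
            cost = protocol.failure_cost
        trace.record(design, cost, acq)

    for _ in range(protocol.n_initial):
        c = float(rng.uniform(space.c_min, space.c_max))
        pattern = space.patterns[rng.integers(len(space.patterns))]
        run_one(DesignParams(c, pattern), "random")

    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * Matern(length_scale=np.ones(6), length_scale_bounds=(1e-2, 1e2), nu=2.5)
        + WhiteKernel(1e-4, (1e-8, 1e-3))
    )

    while len(trace) < protocol.max_iterations:
        # convergence: negligible improvement across the trailing window
        if len(trace) >= protocol.n_initial + protocol.window:
            improvement = (
                trace.best_costs[-protocol.window - 1] - trace.best_costs[-1]
            )
            if improvement < protocol.epsilon:
                trace.termination = "converged"
                return trace

        X = _encode(trace.designs, space)
        y = np.asarray(trace.costs)
        gp = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            n_restarts_optimizer=2,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(X, y)
        # warm-start the marginal-likelihood fit at the previous optimum
        kernel = gp.kernel_

        candidates = _candidate_pool(space, rng)
        mu, sd = gp.predict(_encode(candidates, space), return_std=True)
        acq = ACQUISITIONS[rng.integers(len(ACQUISITIONS))]
        scores = _acquisition_scores(acq, mu, sd, float(np.min(y)))
        proposal = candidates[int(np.argmax(scores))]
        if _is_near_duplicate(proposal, trace.designs, space):
            # degenerate acquisition (e.g. collapsed length scales): fall
            # back to a seeded-random design to keep exploring
            proposal = DesignParams(
                float(rng.uniform(space.c_min, space.c_max)),
                space.patterns[rng.integers(len(space.patterns))],
            )
            acq = "random"
        run_one(proposal, acq)

    trace.termination = "budget"
    return trace


# --------------------------------------------------------------------------
# brute force and restarts
# --------------------------------------------------------------------------


def brute_force(
    space: DesignSpace,
    evaluator: Callable[[DesignParams], float],
    penalty: float = 10.0,
) -> pd.DataFrame:
    """Evaluate every grid design once; errors are recorded as penalties."""
    designs = build_design_grid(space)
    costs = []
    for design in designs:
        try:
            cost = float(evaluator(design))
        except Exception:
            cost = penalty
        costs.append(cost if np.isfinite(cost) else penalty)
    return pd.DataFrame(
        {
            "c": [d.damping_coefficient for d in designs],
            "pattern_mask": [d.mask for d in designs],
            "pattern_names": [d.label() for d in designs],
            "cost": costs,
        }
    )


@dataclass
class RestartResult:
    best_design: DesignParams
    best_cost: float
    traces: list

    @property
    def best_costs(self) -> list[float]:
        return [t.best_cost for t in self.traces]


def run_restarts(
    space: DesignSpace,
    evaluator: Callable[[DesignParams], float],
    protocol: ProtocolConfig | None = None,
    seeds: Sequence[int] | None = None,
) -> RestartResult:
    """Solve the design problem once per seed; keep the best run's design."""
    protocol = protocol or ProtocolConfig()
    if seeds is None:
        seeds = list(range(protocol.n_restarts))
    seeds = list(seeds)
    if len(seeds) < 1:
        raise ValueError("need at least one seed")
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    traces = [bayes_optimize(space, evaluator, protocol, seed=s) for s in seeds]
    finite = [t for t in traces if np.isfinite(t.best_cost)]
    if not finite or all(t.best_cost >= protocol.failure_cost for t in traces):
        raise RuntimeError("all restarts failed")
    best = min(traces, key=lambda t: t.best_cost)
    return RestartResult(best.best_design, best.best_cost, traces)


@dataclass
class RestartSummary:
    median: float
    q25: float
    q75: float
    min: float
    max: float
    values: np.ndarray
    _kde: object = None

    def kde_density(self, xs: np.ndarray) -> np.ndarray:
        if self._kde is None:
            # degenerate sample: unit-mass spike approximated on the grid
            xs = np.asarray(xs, dtype=float)
            out = np.zeros_like(xs)
            i = int(np.argmin(np.abs(xs - self.median)))
            if xs.size > 1:
                out[i] = 1.0 / np.abs(np.gradient(xs)[i])
            return out
        return self._kde(xs)


def summarize_restarts(best_costs: Sequence[float]) -> RestartSummary:
    """Distribution summary (median, quartiles, extremes, Gaussian KDE)."""
    values = np.asarray(list(best_costs), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one cost value")
    kde = None
    if values.size > 1 and np.ptp(values) > 0:
        kde = stats.gaussian_kde(values)
    return RestartSummary(
        median=float(np.median(values)),
        q25=float(np.percentile(values, 25)),
        q75=float(np.percentile(values, 75)),
        min=float(values.min()),
        max=float(values.max()),
        values=values,
        _kde=kde,
    )
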