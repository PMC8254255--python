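"""Orchestration: the recursive optimize-simulate procedure and model runs.

The loop estimates ambulance busy fractions by simulating the current
layout, optimizes station locations with those fractions, simulates the
optimized layout to refresh the fractions, and repeats until the station
distribution stops changing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from emsloc import demand as demand_mod
from emsloc import optimize as opt
from emsloc import simulate as sim
from emsloc.travel import travel_time_matrix

log = logging.getLogger(__name__)

__all__ = [
    "OptimizeConfig",
    "IterationTrace",
    "MODELS",
    "municipalities_frame",
    "solve_model",
    "typed_stations",
    "iterate_optimize_simulate",
    "compare_models",
]

MODELS = ("mexclp_pmp", "pmp", "hierarchical")

# seed offsets of the documented counter scheme: replication seeds are
# master + _SEED_STRIDE * iteration + replication index
_SEED_STRIDE = 1000


@dataclass(frozen=True)
class OptimizeConfig:
    capacity_per_ambulance: float = 3000.0
    T_max: float = 7.0
    q_default: float = 0.3
    convergence_threshold: float = 1.0
    exact_size_limit: int = 250_000  # |I| * |J| above which kernel search is used
    kernel_params: opt.KernelSearchParams = opt.KernelSearchParams()


@dataclass
class IterationTrace:
    iterations: list = field(default_factory=list)
    converged: bool = False

    def record(
        self, q: Mapping, stations: Mapping, objectives: dict, overlap: float | None
    ) -> None:
        vals = np.array(list(q.values()), dtype=float)
        self.iterations.append(
            {
                "q_mean": float(vals.mean()),
                "q_max": float(vals.max()),
                "stations": dict(stations),
                "objectives": objectives,
                "overlap": overlap,
            }
        )

    def __len__(self) -> int:
        return len(self.iterations)


def municipalities_frame(region) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "node_id": m.node_id,
                "pop_0_14": m.pop_0_14,
                "pop_15_64": m.pop_15_64,
                "pop_65plus": m.pop_65plus,
                "current_stations": m.current_stations,
                "current_als": m.current_als,
            }
            for m in region.municipalities
        ]
    )


def solve_model(
    problem: opt.LocationProblem, model: str, config: OptimizeConfig
) -> opt.LocationSolution:
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    big = len(problem.sites) * len(problem.demand_points) > config.exact_size_limit
    if model == "mexclp_pmp":
        if big:
            _, f_star = opt.solve_mexclp(problem)
            sol = opt.kernel_search(
                problem, config.kernel_params, coverage_floor=f_star
            )
            sol.meta["model"] = "mexclp_pmp"
            sol.meta["f_star"] = f_star
            return sol
        return opt.lexicographic_solve(problem)
    if model == "pmp":
        if big:
            sol = opt.kernel_search(problem, config.kernel_params)
            sol.meta["model"] = "pmp"
            return sol
        return opt.solve_weighted_pmedian(problem)
    return opt.solve_hierarchical(problem)


def typed_stations(
    solution: opt.LocationSolution,
    problem: opt.LocationProblem,
    region,
    model: str,
) -> dict:
    """node -> (stations, als) for the simulator, per the model's ALS policy."""
    current_stations = {m.node_id: m.current_stations for m in region.municipalities}
    current_als = {m.node_id: m.current_als for m in region.municipalities}
    if model == "hierarchical" and solution.als_sites:
        sited = {
            i: problem.st.get(i, 0) + int(solution.x.get(i, 0))
            for i in problem.sites
            if problem.st.get(i, 0) + int(solution.x.get(i, 0)) > 0
        }
        als = {i: 0 for i in sited}
        remaining = problem.r
        for i in solution.als_sites:
            take = min(1, sited[i], remaining)
            als[i] = take
            remaining -= take
        # more ALS units than ALS sites: stack extras on the ALS sites
        for i in solution.als_sites:
            if remaining == 0:
                break
            extra = min(sited[i] - als[i], remaining)
            als[i] += extra
            remaining -= extra
        return {i: (sited[i], als[i]) for i in sited}
    return opt.allocate_als_posthoc(solution, problem, current_stations, current_als)


def _station_overlap(a: Mapping, b: Mapping, p: int) -> float:
    common = sum(min(a.get(i, (0,))[0], b.get(i, (0,))[0]) for i in set(a) | set(b))
    return common / p if p else 1.0


def iterate_optimize_simulate(
    region,
    model: str = "pmp",
    opt_config: OptimizeConfig = OptimizeConfig(),
    sim_config: sim.SimulationConfig | None = None,
    max_iters: int = 10,
    seed: int = 0,
    q_override: Mapping | None = None,
) -> tuple[opt.LocationSolution, IterationTrace]:
    """Run the optimize-simulate loop until the station set stabilizes.

    ``q_override`` freezes the busy fractions (the loop then reaches its
    fixed point on the second iteration).  Returns the last solution and
    the full iteration trace.
    """
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    sim_config = sim_config or sim.SimulationConfig(replications=2, horizon_days=7.0)
    matrix = travel_time_matrix(region.network)
    demand_df = demand_mod.demand_table(municipalities_frame(region))
    sites = tuple(m.node_id for m in region.municipalities)

    def estimate_q(stations: Mapping, iteration: int) -> Mapping:
        if q_override is not None:
            return dict(q_override)
        results = [
            sim.run_simulation(
                region, stations, sim_config, seed=seed + _SEED_STRIDE * iteration + k
            )
            for k in range(max(1, sim_config.replications))
        ]
        return sim.estimate_busy_fractions(results, sites, matrix)

    trace = IterationTrace()
    prev_stations = dict(region.station_nodes)
    q = estimate_q(prev_stations, 0)
    solution = None
    for it in range(1, max_iters + 1):
        problem = opt.preprocess_fixed_stations(
            region,
            demand_df,
            capacity_per_ambulance=opt_config.capacity_per_ambulance,
            q=q,
            T_max=opt_config.T_max,
            matrix=matrix,
        )
        solution = solve_model(problem, model, opt_config)
        stations = typed_stations(solution, problem, region, model)
        overlap = _station_overlap(
            prev_stations,
            stations,
            problem.p,
        )
        objectives = {"f": solution.f, "g": solution.g, "g_als": solution.g_als}
        trace.record(q, stations, objectives, overlap)
        if overlap >= opt_config.convergence_threshold:
            trace.converged = True
            break
        prev_stations = stations
        if it < max_iters:
            q = estimate_q(stations, it)
    if not trace.converged:
        log.warning("no convergence in %d iterations (model=%s)", max_iters, model)
    solution.meta["stations"] = trace.iterations[-1]["stations"]
    return solution, trace


def compare_models(
    region,
    models: Sequence[str] = MODELS,
    opt_config: OptimizeConfig = OptimizeConfig(),
    sim_config: sim.SimulationConfig | None = None,
    eval_config: sim.SimulationConfig | None = None,
    max_iters: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Indicator table for the current layout and each optimized layout.

    All layouts are evaluated on identical call streams (common random
    numbers: the same evaluation seed for every row).
    """
    eval_config = eval_config or sim.SimulationConfig(replications=5, horizon_days=14.0)
    eval_seed = seed + 777_000
    rows = []

    def evaluate(name: str, stations: Mapping, extra: dict | None = None) -> None:
        report = sim.run_experiment(region, stations, eval_config, seed=eval_seed)
        rows.append({"layout": name, **report.as_dict(), **(extra or {})})

    evaluate("current", region.station_nodes)
    for model in models:
        solution, trace = iterate_optimize_simulate(
            region,
            model=model,
            opt_config=opt_config,
            sim_config=sim_config,
            max_iters=max_iters,
            seed=seed,
        )
        evaluate(
            model,
            solution.meta["stations"],
            {"g": solution.g, "f": solution.f, "iterations": len(trace)},
        )
    return pd.DataFrame(rows)
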