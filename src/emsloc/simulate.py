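"""Discrete-event EMS simulator.

Calls arrive from a non-homogeneous Poisson process shaped by a 24-hour
profile, land in grid cells proportionally to ambient population, and are
served by the closest available ambulance (with concurrent ALS dispatch
for high-priority calls answered by a BLS unit).  The service pathway is
pre-trip delay, lights-and-sirens travel, on-scene treatment, optional
transport to the nearest compatible hospital, Erlang drop-off and a
standard-speed return during which the unit is dispatchable again.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from emsloc.travel import Mode, Regime, SpeedModel, DEFAULT_SPEED_MODEL, regime_at
from emsloc.travel import edge_travel_time, travel_time_matrix

log = logging.getLogger(__name__)

__all__ = [
    "FHQ",
    "NON_FHQ",
    "SimulationConfig",
    "Call",
    "Ambulance",
    "ReplicationResult",
    "PerformanceReport",
    "generate_calls",
    "run_simulation",
    "run_experiment",
    "compute_indicators",
    "estimate_busy_fractions",
]

FHQ = "FHQ"
NON_FHQ = "non-FHQ"

MINUTES_PER_DAY = 1440.0

# hour-of-day arrival multipliers: peaks 9-11 and 17-21
_DEFAULT_PROFILE = tuple(
    1.5 if 9 <= h < 11 else 1.4 if 17 <= h < 21 else 1.0 for h in range(24)
)


@dataclass(frozen=True)
class SimulationConfig:
    horizon_days: float = 91.0
    replications: int = 10
    mean_daily_calls: float = 60.0
    daily_profile: tuple = _DEFAULT_PROFILE  # 24 hourly multipliers
    pre_trip_delay_min: float = 1.0
    p_transport_bls: float = 0.77
    p_transport_als: float = 0.51
    fhq_probability: float = 0.2651
    # on-scene lognormal means (minutes) by (priority, crew) and one CV
    onscene_mean: Mapping = field(
        default_factory=lambda: {
            (FHQ, "ALS"): 18.0,
            (FHQ, "BLS"): 15.0,
            (NON_FHQ, "ALS"): 14.0,
            (NON_FHQ, "BLS"): 12.0,
        }
    )
    onscene_cv: float = 0.4
    p_pediatric: float = 0.08
    p_cardio: float = 0.12
    secondary_rate_per_day: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_transport_bls", "p_transport_als", "fhq_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.horizon_days <= 0:
            raise ValueError("horizon_days must be > 0")
        if len(self.daily_profile) != 24 or any(m < 0 for m in self.daily_profile):
            raise ValueError("daily_profile needs 24 nonnegative multipliers")


@dataclass
class Call:
    id: int
    arrival_time: float  # minutes from simulation start
    node_id: int
    priority: str
    diagnosis: str = "general"
    cell_id: str | None = None
    municipality_id: int | None = None
    # filled during simulation
    dispatch_time: float | None = None
    first_arrival: float | None = None
    response_time: float | None = None
    served_by: str | None = None  # crew of the transport decision
    transported: bool | None = None
    hospital_id: int | None = None
    units: list = field(default_factory=list)


@dataclass
class Ambulance:
    id: int
    als: bool
    home_node: int
    # runtime state
    state: str = "idle_at_base"
    node: int | None = None
    route: tuple | None = None  # (depart_time, nodes, cum_minutes, mode, regime)
    busy_since: float | None = None
    busy_minutes: float = 0.0
    return_token: int = 0

    def __post_init__(self) -> None:
        self.node = self.home_node

    @property
    def available(self) -> bool:
        return self.state in ("idle_at_base", "returning")


@dataclass
class ReplicationResult:
    calls: list
    workloads: dict  # ambulance id -> busy fraction in [0, 1]
    ambulances: list
    seed: int


@dataclass
class PerformanceReport:
    """The seven performance indicators with replication CIs."""

    mean_response_min: float
    response_ci: tuple
    pct_within_15: float
    n_municipalities_over_15: float
    mean_fhq_response_min: float
    fhq_response_ci: tuple
    pct_fhq_within_8: float
    mean_workload_pct: float
    workload_cv: float
    replications: int = 0
    per_replication: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "response_time_all_min": self.mean_response_min,
            "response_time_all_ci": list(self.response_ci),
            "pct_calls_within_15_min": self.pct_within_15,
            "municipalities_over_15_min": self.n_municipalities_over_15,
            "response_time_fhq_min": self.mean_fhq_response_min,
            "response_time_fhq_ci": list(self.fhq_response_ci),
            "pct_fhq_within_8_min": self.pct_fhq_within_8,
            "avg_workload_pct": self.mean_workload_pct,
            "workload_cv": self.workload_cv,
            "replications": self.replications,
        }


# ---------------------------------------------------------------------------
# Call generation


def _sample_diagnosis(config: SimulationConfig, rng: np.random.Generator) -> str:
    u = rng.random()
    if u < config.p_pediatric:
        return "pediatric"
    if u < config.p_pediatric + config.p_cardio:
        return "cardio"
    return "general"


def generate_calls(
    config: SimulationConfig,
    grid: Sequence,
    horizon_days: float,
    rng: np.random.Generator,
) -> list[Call]:
    """NHPP call stream over the horizon (thinning against the peak rate).

    Cells are sampled proportionally to ambient population; priority and
    diagnosis class are sampled independently per call.
    """
    weights = np.array([c.weight for c in grid], dtype=float)
    total_w = weights.sum()
    if total_w <= 0:
        raise ValueError("grid has zero total population weight")
    probs = weights / total_w

    profile = np.array(config.daily_profile, dtype=float)
    # per-minute rates per hour bin, scaled to the configured daily volume
    scale = config.mean_daily_calls / (profile.sum() * 60.0)
    rate_per_min = profile * scale
    lam_max = rate_per_min.max()
    horizon_min = horizon_days * MINUTES_PER_DAY

    calls: list[Call] = []
    t = 0.0
    cid = 0
    if lam_max <= 0:
        return calls
    while True:
        t += rng.exponential(1.0 / lam_max)
        if t >= horizon_min:
            break
        hour = int((t % MINUTES_PER_DAY) // 60.0)
        if rng.random() * lam_max > rate_per_min[hour]:
            continue
        cell = grid[rng.choice(len(grid), p=probs)]
        priority = FHQ if rng.random() < config.fhq_probability else NON_FHQ
        calls.append(
            Call(
                id=cid,
                arrival_time=t,
                node_id=cell.node_id,
                priority=priority,
                diagnosis=_sample_diagnosis(config, rng),
                cell_id=cell.id,
                municipality_id=cell.municipality_id,
            )
        )
        cid += 1
    return calls


# ---------------------------------------------------------------------------
# Travel support: per-(mode, regime) matrices, paths and edge times


class _SimTravel:
    def __init__(self, network, speed_model: SpeedModel = DEFAULT_SPEED_MODEL):
        self.network = network
        self._dist: dict = {}
        self._path: dict = {}
        self._edge: dict = {}
        import networkx as nx

        for mode in Mode:
            for regime in Regime:
                g = nx.Graph()
                g.add_nodes_from(network.nodes)
                for a, b, data in network.edges(data=True):
                    minutes = edge_travel_time(
                        data["length_km"],
                        data["category"],
                        data["urban"],
                        mode,
                        regime,
                        speed_model,
                    )
                    g.add_edge(a, b, minutes=minutes)
                    self._edge[(mode, regime, a, b)] = minutes
                    self._edge[(mode, regime, b, a)] = minutes
                dist = {}
                path = {}
                for src, (d, p) in nx.all_pairs_dijkstra(g, weight="minutes"):
                    dist[src] = d
                    path[src] = p
                self._dist[(mode, regime)] = dist
                self._path[(mode, regime)] = path

    def time(self, o, d, mode: Mode, regime: Regime) -> float:
        return self._dist[(mode, regime)][o].get(d, math.inf)

    def path(self, o, d, mode: Mode, regime: Regime) -> list:
        return self._path[(mode, regime)][o][d]

    def edge_minutes(self, a, b, mode: Mode, regime: Regime) -> float:
        return self._edge[(mode, regime, a, b)]

    def route(self, o, d, depart: float, mode: Mode, regime: Regime) -> tuple:
        nodes = self.path(o, d, mode, regime)
        cum = [0.0]
        for a, b in zip(nodes, nodes[1:]):
            cum.append(cum[-1] + self.edge_minutes(a, b, mode, regime))
        return (depart, nodes, cum, mode, regime)


def _position_on_route(route: tuple, t: float):
    """(node_a, node_b, fraction_of_edge) of a moving unit at clock t."""
    depart, nodes, cum, _, _ = route
    elapsed = t - depart
    if elapsed <= 0:
        return (nodes[0], nodes[0], 0.0)
    if elapsed >= cum[-1]:
        return (nodes[-1], nodes[-1], 0.0)
    k = int(np.searchsorted(cum, elapsed, side="right")) - 1
    seg = cum[k + 1] - cum[k]
    frac = (elapsed - cum[k]) / seg if seg > 0 else 0.0
    return (nodes[k], nodes[k + 1], frac)


# ---------------------------------------------------------------------------
# The engine


class _Engine:
    def __init__(self, region, stations: Mapping, config: SimulationConfig, rng):
        self.region = region
        self.config = config
        self.rng = rng
        self.travel = _SimTravel(region.network)
        self.ambulances: list[Ambulance] = []
        aid = 0
        for node in sorted(stations):
            count, n_als = stations[node]
            for k in range(count):
                self.ambulances.append(
                    Ambulance(id=aid, als=k < n_als, home_node=node)
                )
                aid += 1
        if not self.ambulances:
            raise ValueError("no stations: at least one ambulance is required")
        self.events: list = []
        self.seq = 0
        self.queue: list[Call] = []
        self.clock = 0.0
        self.completed: set = set()
        self.scene_end: dict = {}
        self.arrived: dict = {}
        self._hospital_warned: set = set()

    # -- event plumbing ------------------------------------------------

    def push(self, t: float, kind: str, payload: tuple) -> None:
        heapq.heappush(self.events, (t, self.seq, kind, payload))
        self.seq += 1

    def run(self, calls: Sequence[Call]) -> None:
        for call in calls:
            self.push(call.arrival_time, "call", (call,))
        if self.config.secondary_rate_per_day > 0:
            t = 0.0
            horizon = self.config.horizon_days * MINUTES_PER_DAY
            rate = self.config.secondary_rate_per_day / MINUTES_PER_DAY
            while True:
                t += self.rng.exponential(1.0 / rate)
                if t >= horizon:
                    break
                self.push(t, "secondary", ())
        while self.events:
            t, _, kind, payload = heapq.heappop(self.events)
            assert t >= self.clock - 1e-9, "event clock must be monotone"
            self.clock = t
            getattr(self, f"_on_{kind}")(t, *payload)

    # -- travel helpers ------------------------------------------------

    def _regime(self, t: float) -> Regime:
        return regime_at((t % MINUTES_PER_DAY) / 60.0)

    def _response_time_from(self, amb: Ambulance, target, t: float) -> float:
        """Lights-and-sirens travel minutes from the unit's current position."""
        regime = self._regime(t)
        if amb.state == "returning" and amb.route is not None:
            a, b, frac = _position_on_route(amb.route, t)
            if a == b:
                return self.travel.time(a, target, Mode.LIGHTS_SIRENS, regime)
            e = self.travel.edge_minutes(a, b, Mode.LIGHTS_SIRENS, regime)
            via_a = frac * e + self.travel.time(a, target, Mode.LIGHTS_SIRENS, regime)
            via_b = (1 - frac) * e + self.travel.time(
                b, target, Mode.LIGHTS_SIRENS, regime
            )
            return min(via_a, via_b)
        return self.travel.time(amb.node, target, Mode.LIGHTS_SIRENS, regime)

    def _route_to(self, amb: Ambulance, target, t: float, mode: Mode) -> float:
        """Set the unit's route to target; returns the travel minutes."""
        regime = self._regime(t)
        if amb.state == "returning" and amb.route is not None:
            a, b, frac = _position_on_route(amb.route, t)
            if a != b:
                e = self.travel.edge_minutes(a, b, mode, regime)
                via_a = frac * e + self.travel.time(a, target, mode, regime)
                via_b = (1 - frac) * e + self.travel.time(b, target, mode, regime)
                start, lead = (a, frac * e) if via_a <= via_b else (b, (1 - frac) * e)
                base = self.travel.route(start, target, t + lead, mode, regime)
                amb.route = base
                return lead + base[2][-1]
            amb.node = a
        minutes = self.travel.time(amb.node, target, mode, regime)
        amb.route = self.travel.route(amb.node, target, t, mode, regime)
        return minutes

    # -- dispatching ---------------------------------------------------

    def _available(self) -> list[Ambulance]:
        return [a for a in self.ambulances if a.available]

    def _dispatch_unit(self, amb: Ambulance, call: Call, t: float) -> None:
        travel = self._route_to(amb, call.node_id, t, Mode.LIGHTS_SIRENS)
        amb.state = "en_route_to_scene"
        amb.busy_since = t
        amb.return_token += 1  # invalidate any pending arrive-home event
        call.units.append(amb.id)
        arrive = t + self.config.pre_trip_delay_min + travel
        self.push(arrive, "arrive_scene", (amb, call))

    def try_dispatch(self, call: Call, t: float) -> bool:
        avail = self._available()
        if not avail:
            return False
        primary = min(
            avail, key=lambda a: (self._response_time_from(a, call.node_id, t), a.id)
        )
        call.dispatch_time = t
        self._dispatch_unit(primary, call, t)
        if call.priority == FHQ and not primary.als:
            als_avail = [a for a in self._available() if a.als]
            if als_avail:
                backup = min(
                    als_avail,
                    key=lambda a: (self._response_time_from(a, call.node_id, t), a.id),
                )
                self._dispatch_unit(backup, call, t)
        return True

    def _drain_queue(self, t: float) -> None:
        # high-priority first, FIFO within class
        self.queue.sort(key=lambda c: (c.priority != FHQ, c.arrival_time))
        remaining = []
        for call in self.queue:
            if not self._available() or not self.try_dispatch(call, t):
                remaining.append(call)
        self.queue = remaining

    # -- event handlers ------------------------------------------------

    def _on_call(self, t: float, call: Call) -> None:
        if not self.try_dispatch(call, t):
            self.queue.append(call)

    def _on_arrive_scene(self, t: float, amb: Ambulance, call: Call) -> None:
        amb.node = call.node_id
        amb.route = None
        if call.id in self.completed:  # scene wrapped up before this unit arrived
            self._release(amb, t, call.node_id)
            return
        self.arrived.setdefault(call.id, []).append(amb)
        amb.state = "on_scene"
        if call.first_arrival is None:
            call.first_arrival = t
            call.response_time = t - call.arrival_time
            crew = "ALS" if any(self._amb(u).als for u in call.units) else "BLS"
            mean = self.config.onscene_mean[(call.priority, crew)]
            duration = _lognormal(mean, self.config.onscene_cv, self.rng)
            end = t + duration
            self.scene_end[call.id] = end
            self.push(end, "scene_done", (call,))

    def _amb(self, aid: int) -> Ambulance:
        return self.ambulances[aid]

    def _on_scene_done(self, t: float, call: Call) -> None:
        self.completed.add(call.id)
        on_scene = self.arrived.get(call.id, [])
        physician = any(a.als for a in on_scene)
        call.served_by = "ALS" if physician else "BLS"
        p = self.config.p_transport_als if physician else self.config.p_transport_bls
        call.transported = bool(self.rng.random() < p)
        if call.transported and self.region.hospitals:
            hospital = self._choose_hospital(call, t)
            call.hospital_id = hospital.id
            transporter = next(
                (a for a in on_scene if a.als), on_scene[0] if on_scene else None
            )
            for a in on_scene:
                if a is not transporter:
                    self._release(a, t, call.node_id)
            if transporter is not None:
                travel = self._route_to(
                    transporter, hospital.node_id, t, Mode.LIGHTS_SIRENS
                )
                transporter.state = "transporting"
                self.push(t + travel, "arrive_hospital", (transporter, call, hospital))
            return
        call.transported = call.transported and bool(self.region.hospitals)
        for a in on_scene:
            self._release(a, t, call.node_id)

    def _choose_hospital(self, call: Call, t: float):
        regime = self._regime(t)
        needed = call.diagnosis if call.diagnosis in ("pediatric", "cardio") else "general"
        compatible = [
            h for h in self.region.hospitals if needed in h.specializations
        ]
        if not compatible:
            if needed not in self._hospital_warned:
                log.warning(
                    "no %s-compatible hospital; falling back to nearest general",
                    needed,
                )
                self._hospital_warned.add(needed)
            compatible = [
                h for h in self.region.hospitals if "general" in h.specializations
            ] or list(self.region.hospitals)
        return min(
            compatible,
            key=lambda h: (
                self.travel.time(call.node_id, h.node_id, Mode.LIGHTS_SIRENS, regime),
                h.id,
            ),
        )

    def _on_arrive_hospital(self, t: float, amb: Ambulance, call: Call, hospital) -> None:
        amb.node = hospital.node_id
        amb.route = None
        amb.state = "at_hospital"
        dropoff = self.rng.gamma(
            hospital.dropoff_shape, hospital.dropoff_mean / hospital.dropoff_shape
        )
        self.push(t + dropoff, "dropoff_done", (amb, call, hospital))

    def _on_dropoff_done(self, t: float, amb: Ambulance, call: Call, hospital) -> None:
        self._release(amb, t, hospital.node_id)

    def _release(self, amb: Ambulance, t: float, node) -> None:
        """Unit finishes patient-committed work and heads home, dispatchable."""
        if amb.busy_since is not None:
            amb.busy_minutes += t - amb.busy_since
            amb.busy_since = None
        amb.node = node
        amb.state = "returning"
        amb.return_token += 1
        token = amb.return_token
        travel = self._route_to(amb, amb.home_node, t, Mode.STANDARD)
        self.push(t + travel, "arrive_home", (amb, token))
        self._drain_queue(t)

    def _on_arrive_home(self, t: float, amb: Ambulance, token: int) -> None:
        if amb.state == "returning" and amb.return_token == token:
            amb.state = "idle_at_base"
            amb.node = amb.home_node
            amb.route = None

    def _on_secondary(self, t: float) -> None:
        hospitals = self.region.hospitals
        if len(hospitals) < 2:
            return
        idle_bls = [
            a for a in self.ambulances if a.state == "idle_at_base" and not a.als
        ]
        idx = self.rng.choice(len(hospitals), size=2, replace=False)
        src, dst = hospitals[int(idx[0])], hospitals[int(idx[1])]
        if not idle_bls:
            return
        regime = self._regime(t)
        amb = min(
            idle_bls,
            key=lambda a: (
                self.travel.time(a.node, src.node_id, Mode.STANDARD, regime),
                a.id,
            ),
        )
        amb.busy_since = t
        amb.state = "transporting"
        leg1 = self.travel.time(amb.node, src.node_id, Mode.STANDARD, regime)
        leg2 = self.travel.time(src.node_id, dst.node_id, Mode.STANDARD, regime)
        self.push(t + leg1 + leg2, "secondary_done", (amb, dst))

    def _on_secondary_done(self, t: float, amb: Ambulance, hospital) -> None:
        self._release(amb, t, hospital.node_id)


def _lognormal(mean: float, cv: float, rng: np.random.Generator) -> float:
    if mean <= 0:
        return 0.0
    if cv <= 0:
        return mean
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


# ---------------------------------------------------------------------------
# Public entry points


def run_simulation(
    region,
    stations: Mapping,
    config: SimulationConfig,
    seed: int,
    call_script: Sequence | None = None,
) -> ReplicationResult:
    """One replication; deterministic given the seed.

    ``stations`` maps node -> (ambulance count, ALS count).  A
    ``call_script`` (e.g. from :func:`emsloc.fixtures.generate_call_script`)
    replaces the stochastic call generator.
    """
    rng = np.random.default_rng(seed)
    engine = _Engine(region, stations, config, rng)
    if call_script is not None:
        cell_of = {c.node_id: c for c in region.grid}
        calls = []
        for k, sc in enumerate(call_script):
            cell = cell_of.get(sc.node_id)
            calls.append(
                Call(
                    id=k,
                    arrival_time=sc.time_min,
                    node_id=sc.node_id,
                    priority=sc.priority,
                    diagnosis=getattr(sc, "diagnosis", "general"),
                    cell_id=cell.id if cell else None,
                    municipality_id=cell.municipality_id if cell else None,
                )
            )
    else:
        calls = generate_calls(config, region.grid, config.horizon_days, rng)
    engine.run(calls)
    horizon_min = config.horizon_days * MINUTES_PER_DAY
    workloads = {
        a.id: min(1.0, a.busy_minutes / horizon_min) for a in engine.ambulances
    }
    return ReplicationResult(
        calls=calls, workloads=workloads, ambulances=engine.ambulances, seed=seed
    )


def compute_indicators(calls: Sequence[Call], workloads: Mapping) -> dict:
    """The seven performance indicators for one replication."""
    served = [c for c in calls if c.response_time is not None]
    if not served:
        return {
            "zero_calls": True,
            "response_time_all_min": math.nan,
            "pct_calls_within_15_min": math.nan,
            "municipalities_over_15_min": 0,
            "response_time_fhq_min": math.nan,
            "pct_fhq_within_8_min": math.nan,
            "avg_workload_pct": 100.0 * float(np.mean(list(workloads.values()))),
            "workload_cv": _workload_cv(workloads),
        }
    rt = np.array([c.response_time for c in served])
    fhq = np.array([c.response_time for c in served if c.priority == FHQ])
    by_muni: dict = {}
    for c in served:
        by_muni.setdefault(c.municipality_id, []).append(c.response_time)
    over15 = sum(1 for v in by_muni.values() if np.mean(v) > 15.0)
    return {
        "zero_calls": False,
        "response_time_all_min": float(rt.mean()),
        "pct_calls_within_15_min": 100.0 * float((rt <= 15.0).mean()),
        "municipalities_over_15_min": int(over15),
        "response_time_fhq_min": float(fhq.mean()) if fhq.size else math.nan,
        "pct_fhq_within_8_min": 100.0 * float((fhq <= 8.0).mean())
        if fhq.size
        else math.nan,
        "avg_workload_pct": 100.0 * float(np.mean(list(workloads.values()))),
        "workload_cv": _workload_cv(workloads),
    }


def _workload_cv(workloads: Mapping) -> float:
    vals = np.array(list(workloads.values()), dtype=float)
    mean = vals.mean()
    if mean == 0:
        return 0.0
    return float(vals.std() / mean)  # population sd


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple:
    n = len(values)
    mean = float(values.mean())
    if n < 2 or np.allclose(values, values[0]):
        return (mean, mean)
    half = stats.t.ppf(0.5 + level / 2.0, n - 1) * values.std(ddof=1) / math.sqrt(n)
    return (mean - float(half), mean + float(half))


def run_experiment(
    region, stations: Mapping, config: SimulationConfig, seed: int | None = None
) -> PerformanceReport:
    """Replicated simulation with Student-t confidence intervals.

    Replication seeds are ``seed + k`` for k = 0..replications-1.
    """
    if config.replications < 2:
        raise ValueError("at least 2 replications are needed for CIs")
    seed = config.seed if seed is None else seed
    rows = []
    for k in range(config.replications):
        res = run_simulation(region, stations, config, seed=seed + k)
        rows.append(compute_indicators(res.calls, res.workloads))
    resp = np.array([r["response_time_all_min"] for r in rows])
    fhq = np.array([r["response_time_fhq_min"] for r in rows])
    return PerformanceReport(
        mean_response_min=float(np.nanmean(resp)),
        response_ci=_t_ci(resp[~np.isnan(resp)]) if np.isfinite(resp).any() else (math.nan, math.nan),
        pct_within_15=float(np.nanmean([r["pct_calls_within_15_min"] for r in rows])),
        n_municipalities_over_15=float(
            np.mean([r["municipalities_over_15_min"] for r in rows])
        ),
        mean_fhq_response_min=float(np.nanmean(fhq)),
        fhq_response_ci=_t_ci(fhq[~np.isnan(fhq)]) if np.isfinite(fhq).any() else (math.nan, math.nan),
        pct_fhq_within_8=float(np.nanmean([r["pct_fhq_within_8_min"] for r in rows])),
        mean_workload_pct=float(np.mean([r["avg_workload_pct"] for r in rows])),
        workload_cv=float(np.mean([r["workload_cv"] for r in rows])),
        replications=config.replications,
        per_replication=rows,
    )


def estimate_busy_fractions(
    results: Sequence[ReplicationResult],
    candidates: Sequence,
    matrix,
    neighbourhood_min: float = 30.0,
    eps: float = 1e-6,
) -> dict:
    """Candidate busy probabilities from simulated workloads.

    A candidate hosting stations gets the mean workload of its own
    ambulances; a stationless candidate the mean workload of stations
    within ``neighbourhood_min`` travel minutes; with none in reach, the
    global mean.  Values are clamped to [0, 1-eps].
    """
    if not results:
        raise ValueError("at least one replication result is required")
    node_loads: dict = {}
    for res in results:
        for amb in res.ambulances:
            node_loads.setdefault(amb.home_node, []).append(res.workloads[amb.id])
    station_means = {n: float(np.mean(v)) for n, v in node_loads.items()}
    global_mean = float(np.mean([w for v in node_loads.values() for w in v]))
    q = {}
    for cand in candidates:
        if cand in station_means:
            val = station_means[cand]
        else:
            near = [
                station_means[n]
                for n in station_means
                if matrix.times[cand][n] <= neighbourhood_min
            ]
            val = float(np.mean(near)) if near else global_mean
        q[cand] = min(max(val, 0.0), 1.0 - eps)
    return q
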