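"""MILP station-location models and the kernel-search matheuristic.

Three models share one :class:`LocationProblem`:

* expected-coverage maximization (``solve_mexclp``): maximize expected
  high-priority demand covered within ``T_max`` discounting ambulance
  unavailability ``q_j`` via marginal gains ``(1-q)q^(k-1)``;
* weighted p-median (``solve_weighted_pmedian``): minimize demand-weighted
  travel time, optionally under a coverage floor (the lexicographic
  second stage);
* hierarchical two-tier median (``solve_hierarchical``): the p-median
  lower level picks p stations, the upper level picks the r ALS sites
  among them minimizing ALS-weighted travel time.

All solvers break objective ties deterministically toward the lowest site
index by a secondary lexicographic solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

__all__ = [
    "LocationProblem",
    "LocationSolution",
    "KernelSearchParams",
    "InfeasibleProblemError",
    "preprocess_fixed_stations",
    "solve_mexclp",
    "expected_coverage",
    "solve_weighted_pmedian",
    "lexicographic_solve",
    "solve_hierarchical",
    "kernel_search",
    "allocate_als_posthoc",
    "total_weighted_time",
]

_FLOOR_SLACK = 1e-6  # relative slack on the lexicographic coverage floor
_TIE_TOL = 1e-7


class InfeasibleProblemError(RuntimeError):
    """Raised when a location model has no feasible solution."""


@dataclass(frozen=True)
class LocationProblem:
    """All sets and parameters of the siting models.

    ``sites`` is the ordered candidate set I; ``open_sites`` the subset
    where a new station may still be placed (at most one per site);
    ``I1`` the fixed sites with spare capacity that may serve other
    demand points; ``st`` maps site -> number of fixed stations.
    """

    sites: tuple
    demand_points: tuple
    t: Mapping  # t[i][j] minutes
    b: Mapping
    b_fhq: Mapping
    q: Mapping
    p: int
    r: int = 0
    st: Mapping = field(default_factory=dict)
    I1: frozenset = frozenset()
    open_sites: tuple | None = None
    T_max: float = 7.0

    def __post_init__(self) -> None:
        if self.open_sites is None:
            object.__setattr__(
                self,
                "open_sites",
                tuple(i for i in self.sites if self.st.get(i, 0) == 0),
            )
        if self.p < self.total_fixed:
            raise InfeasibleProblemError(
                f"p={self.p} below the number of fixed stations {self.total_fixed}"
            )
        for j in self.demand_points:
            qj = self.q.get(j, 0.0)
            if not 0.0 <= qj < 1.0:
                raise ValueError(f"q[{j!r}]={qj} must lie in [0, 1)")

    @property
    def total_fixed(self) -> int:
        return sum(self.st.get(i, 0) for i in self.sites)

    @property
    def p_new(self) -> int:
        """Stations still to be sited among ``open_sites``."""
        return self.p - self.total_fixed

    def N(self, j) -> tuple:
        return tuple(i for i in self.sites if self.t[i][j] <= self.T_max)

    def n(self, j) -> int:
        return len(self.N(j))

    def coverage_coeffs(self, j) -> np.ndarray:
        """Marginal coverage gains b_fhq * (1-q) q^(k-1), k = 1..n_j."""
        qj = self.q.get(j, 0.0)
        nj = self.n(j)
        k = np.arange(1, nj + 1)
        return self.b_fhq[j] * (1.0 - qj) * qj ** (k - 1)


@dataclass
class LocationSolution:
    """Sited stations and demand assignments with objective values."""

    x: dict  # site -> 0/1 new station
    assignment: dict  # demand point -> serving site
    f: float  # expected high-priority coverage
    g: float  # total demand-weighted travel time (minutes * patients)
    als_sites: tuple = ()
    als_assignment: dict = field(default_factory=dict)
    g_als: float = math.nan
    meta: dict = field(default_factory=dict)

    @property
    def open_sites(self) -> tuple:
        return tuple(i for i, v in self.x.items() if v)


# ---------------------------------------------------------------------------
# MILP plumbing


class _Milp:
    """Small dense MILP builder around scipy.optimize.milp."""

    def __init__(self, n_vars: int, integrality: np.ndarray):
        self.n = n_vars
        self.integrality = integrality
        self.rows: list[np.ndarray] = []
        self.lbs: list[float] = []
        self.ubs: list[float] = []

    def add(self, row: np.ndarray, lb: float, ub: float) -> None:
        self.rows.append(row)
        self.lbs.append(lb)
        self.ubs.append(ub)

    def _constraints(self) -> list[LinearConstraint]:
        if not self.rows:
            return []
        return [
            LinearConstraint(np.vstack(self.rows), np.array(self.lbs), np.array(self.ubs))
        ]

    def solve(self, c: np.ndarray, time_limit: float | None = None):
        options = {} if time_limit is None else {"time_limit": time_limit}
        res = milp(
            c=c,
            integrality=self.integrality,
            bounds=Bounds(0.0, 1.0),
            constraints=self._constraints(),
            options=options,
        )
        return res

    def solve_lp(self, c: np.ndarray):
        """LP relaxation via linprog (exposes reduced costs)."""
        A_rows, b = [], []
        for row, lb, ub in zip(self.rows, self.lbs, self.ubs):
            if math.isfinite(ub):
                A_rows.append(row)
                b.append(ub)
            if math.isfinite(lb):
                A_rows.append(-row)
                b.append(-lb)
        res = linprog(
            c=c,
            A_ub=np.vstack(A_rows) if A_rows else None,
            b_ub=np.array(b) if A_rows else None,
            bounds=[(0.0, 1.0)] * self.n,
            method="highs",
        )
        return res

    def solve_canonical(
        self,
        c: np.ndarray,
        tie_cost: np.ndarray,
        time_limit: float | None = None,
    ):
        """Optimize ``c``, then break ties by minimizing ``tie_cost``.

        The second solve constrains the primary objective to its optimum
        (plus a tiny tolerance) and minimizes the tie cost, making the
        returned vertex deterministic regardless of solver internals.
        """
        res = self.solve(c, time_limit)
        if res.status != 0:
            return res
        v = float(c @ res.x)
        tol = _TIE_TOL * (1.0 + abs(v))
        self.add(c, -np.inf, v + tol)
        res2 = self.solve(tie_cost, time_limit)
        self.rows.pop(), self.lbs.pop(), self.ubs.pop()
        return res2 if res2.status == 0 else res


def _check(res, what: str) -> None:
    if res.status != 0:
        raise InfeasibleProblemError(f"{what}: solver status {res.status} ({res.message})")


# ---------------------------------------------------------------------------
# Preprocessing


def preprocess_fixed_stations(
    region,
    demand_df,
    capacity_per_ambulance: float = 3000.0,
    q: Mapping | float = 0.3,
    T_max: float = 7.0,
    matrix=None,
    r: int | None = None,
) -> LocationProblem:
    """Build a :class:`LocationProblem` from a region, fixing engaged stations.

    Two rules decide which current stations stay put:

    * a town whose annual demand exceeds the joint capacity of its current
      stations keeps all of them (site removed from the relocatable set,
      demand reduced by the capacity served);
    * a town with several stations but demand below one station's capacity
      keeps one station with spare capacity (site joins I1), the rest are
      freed for relocation.

    ``q`` may be a constant busy fraction or a per-demand-point mapping.
    """
    from emsloc.travel import travel_time_matrix

    if capacity_per_ambulance <= 0:
        raise ValueError("capacity_per_ambulance must be > 0")
    if matrix is None:
        matrix = travel_time_matrix(region.network)
    demand = demand_df.set_index("id")

    sites = tuple(m.node_id for m in region.municipalities)
    st: dict = {}
    I1 = set()
    b: dict = {}
    b_fhq: dict = {}
    p = 0
    r_total = 0
    for m in region.municipalities:
        bj = float(demand.loc[m.id, "b_j"])
        b_fhq[m.node_id] = float(demand.loc[m.id, "b_fhq_j"])
        c = m.current_stations
        p += c
        r_total += m.current_als
        if c > 0 and bj > capacity_per_ambulance * c:
            st[m.node_id] = c
            bj = max(0.0, bj - capacity_per_ambulance * c)
        elif c > 1 and bj < capacity_per_ambulance:
            st[m.node_id] = 1
            I1.add(m.node_id)
        b[m.node_id] = bj

    qmap = (
        {j: float(q) for j in sites} if not isinstance(q, Mapping) else dict(q)
    )
    return LocationProblem(
        sites=sites,
        demand_points=sites,
        t=matrix.times,
        b=b,
        b_fhq=b_fhq,
        q=qmap,
        p=p,
        r=r_total if r is None else r,
        st=st,
        I1=frozenset(I1),
        T_max=T_max,
    )


# ---------------------------------------------------------------------------
# Expected-coverage model


def _mexclp_milp(problem: LocationProblem):
    opens = list(problem.open_sites)
    m = len(opens)
    y_index: dict = {}
    for j in problem.demand_points:
        for k in range(problem.n(j)):
            y_index[(j, k)] = m + len(y_index)
    n_vars = m + len(y_index)
    # y relaxed to [0,1]: strictly decreasing marginal gains make it integral
    # at the optimum whenever 0 < q < 1, and its value never affects x
    integrality = np.zeros(n_vars)
    integrality[:m] = 1

    model = _Milp(n_vars, integrality)
    c = np.zeros(n_vars)
    for j in problem.demand_points:
        coeffs = problem.coverage_coeffs(j)
        for k, gain in enumerate(coeffs):
            c[y_index[(j, k)]] = -gain  # maximize
        row = np.zeros(n_vars)
        fixed_in_nj = 0
        for i in problem.N(j):
            fixed_in_nj += problem.st.get(i, 0)
            if i in problem.open_sites:
                row[opens.index(i)] = -1.0
        for k in range(problem.n(j)):
            row[y_index[(j, k)]] = 1.0
        model.add(row, -np.inf, float(fixed_in_nj))
    row = np.zeros(n_vars)
    row[:m] = 1.0
    model.add(row, problem.p_new, problem.p_new)
    return model, c, opens, y_index


def solve_mexclp(problem: LocationProblem) -> tuple[dict, float]:
    """Optimal new-station vector maximizing expected covered FHQ demand.

    Returns ``(x, f_star)`` where ``x`` maps every site to 0/1 (new
    stations only; fixed stations live in ``problem.st``).
    """
    if problem.p_new > len(problem.open_sites):
        raise InfeasibleProblemError(
            f"cannot place {problem.p_new} new stations on "
            f"{len(problem.open_sites)} open sites"
        )
    model, c, opens, _ = _mexclp_milp(problem)
    tie = np.zeros(model.n)
    tie[: len(opens)] = 1.0 + np.arange(len(opens))
    res = model.solve_canonical(c, tie)
    _check(res, "expected-coverage model")
    x = {i: 0 for i in problem.sites}
    for idx, i in enumerate(opens):
        x[i] = int(round(res.x[idx]))
    return x, expected_coverage(x, problem)


def expected_coverage(x: Mapping, problem: LocationProblem) -> float:
    """Closed-form expected coverage of a station vector.

    ``f = sum_j b_fhq_j * (1 - q_j^m_j)`` with ``m_j`` the number of
    stations (new + fixed) in the neighbourhood of j, capped at ``n_j``
    (the model only rewards up to one station per neighbourhood site).
    """
    f = 0.0
    for j in problem.demand_points:
        m_j = sum(int(x.get(i, 0)) + problem.st.get(i, 0) for i in problem.N(j))
        m_j = min(m_j, problem.n(j))
        qj = problem.q.get(j, 0.0)
        f += problem.b_fhq[j] * (1.0 - qj**m_j)
    return f


# ---------------------------------------------------------------------------
# Weighted p-median


def _servers(problem: LocationProblem, x: Mapping) -> list:
    return [
        i
        for i in problem.sites
        if x.get(i, 0) or i in problem.I1
    ]


def _nearest_assignment(problem: LocationProblem, servers: Sequence) -> dict:
    """Each demand point to its nearest server; ties to the lowest index."""
    if not servers:
        raise InfeasibleProblemError("no serving site is open")
    order = {i: idx for idx, i in enumerate(problem.sites)}
    assignment = {}
    for j in problem.demand_points:
        best = min(servers, key=lambda i: (problem.t[i][j], order[i]))
        if math.isinf(problem.t[best][j]):
            raise InfeasibleProblemError(f"demand point {j!r} unreachable")
        assignment[j] = best
    return assignment


def _pmedian_milp(problem: LocationProblem, coverage_floor: float | None):
    opens = list(problem.open_sites)
    servers = list(dict.fromkeys(opens + sorted(problem.I1, key=list(problem.sites).index)))
    m = len(opens)
    z_index = {}
    for i in servers:
        for j in problem.demand_points:
            z_index[(i, j)] = m + len(z_index)
    n_z = len(z_index)
    y_index: dict = {}
    if coverage_floor is not None:
        for j in problem.demand_points:
            for k in range(problem.n(j)):
                y_index[(j, k)] = m + n_z + len(y_index)
    n_vars = m + n_z + len(y_index)
    integrality = np.zeros(n_vars)
    integrality[:m] = 1  # z and y are integral at the optimum when x is

    model = _Milp(n_vars, integrality)
    c = np.zeros(n_vars)
    for (i, j), idx in z_index.items():
        c[idx] = problem.t[i][j] * problem.b[j]
    for j in problem.demand_points:  # (6)
        row = np.zeros(n_vars)
        for i in servers:
            row[z_index[(i, j)]] = 1.0
        model.add(row, 1.0, 1.0)
    for i in servers:  # (7); fixed spare-capacity sites are unconstrained (8)
        if i in problem.I1:
            continue
        for j in problem.demand_points:
            row = np.zeros(n_vars)
            row[z_index[(i, j)]] = 1.0
            row[opens.index(i)] = -1.0
            model.add(row, -np.inf, 0.0)
    row = np.zeros(n_vars)  # (9)
    row[:m] = 1.0
    model.add(row, problem.p_new, problem.p_new)
    if coverage_floor is not None:  # (5) + (13)
        floor_row = np.zeros(n_vars)
        for j in problem.demand_points:
            coeffs = problem.coverage_coeffs(j)
            row = np.zeros(n_vars)
            fixed_in_nj = 0
            for i in problem.N(j):
                fixed_in_nj += problem.st.get(i, 0)
                if i in problem.open_sites:
                    row[opens.index(i)] = -1.0
            for k in range(problem.n(j)):
                row[y_index[(j, k)]] = 1.0
                floor_row[y_index[(j, k)]] = coeffs[k]
            model.add(row, -np.inf, float(fixed_in_nj))
        model.add(
            floor_row, coverage_floor * (1.0 - _FLOOR_SLACK), np.inf
        )
    return model, c, opens


def solve_weighted_pmedian(
    problem: LocationProblem,
    coverage_floor: float | None = None,
    time_limit: float | None = None,
) -> LocationSolution:
    """Minimize total demand-weighted travel time with p stations.

    With ``coverage_floor`` the expected-coverage value may not drop below
    the floor (lexicographic second stage).  In the returned solution every
    demand point is assigned to its nearest open or spare-capacity site.
    """
    if problem.p_new > len(problem.open_sites):
        raise InfeasibleProblemError(
            f"cannot place {problem.p_new} new stations on "
            f"{len(problem.open_sites)} open sites"
        )
    model, c, opens = _pmedian_milp(problem, coverage_floor)
    tie = np.zeros(model.n)
    tie[: len(opens)] = 1.0 + np.arange(len(opens))
    res = model.solve_canonical(c, tie, time_limit)
    if res.status != 0 and coverage_floor is not None:
        raise InfeasibleProblemError(
            f"coverage floor {coverage_floor} unattainable (status {res.status})"
        )
    _check(res, "weighted p-median")
    x = {i: 0 for i in problem.sites}
    for idx, i in enumerate(opens):
        x[i] = int(round(res.x[idx]))
    assignment = _nearest_assignment(problem, _servers(problem, x))
    g = total_weighted_time(assignment, problem)
    return LocationSolution(
        x=x,
        assignment=assignment,
        f=expected_coverage(x, problem),
        g=g,
        meta={"model": "pmp", "coverage_floor": coverage_floor},
    )


def lexicographic_solve(problem: LocationProblem) -> LocationSolution:
    """Coverage first, then travel time under the coverage floor."""
    _, f_star = solve_mexclp(problem)
    sol = solve_weighted_pmedian(problem, coverage_floor=f_star)
    sol.meta["model"] = "mexclp_pmp"
    sol.meta["f_star"] = f_star
    return sol


# ---------------------------------------------------------------------------
# Hierarchical two-tier model


def solve_hierarchical(
    problem: LocationProblem, time_limit: float | None = None
) -> LocationSolution:
    """p-median lower level, then site r ALS units among the open stations.

    The upper level minimizes ALS-weighted travel time over sites with a
    station (new or fixed); ties break to the lowest site index.
    """
    if problem.r > problem.p:
        raise InfeasibleProblemError(f"r={problem.r} exceeds p={problem.p}")
    sol = solve_weighted_pmedian(problem, time_limit=time_limit)
    stationed = [
        i for i in problem.sites if sol.x.get(i, 0) or problem.st.get(i, 0) > 0
    ]
    if problem.r > len(stationed):
        raise InfeasibleProblemError(
            f"r={problem.r} exceeds the {len(stationed)} sites with stations"
        )
    if problem.r == 0:
        sol.meta["model"] = "hierarchical"
        return sol

    m = len(stationed)
    v_index = {}
    for i in stationed:
        for j in problem.demand_points:
            v_index[(i, j)] = m + len(v_index)
    n_vars = m + len(v_index)
    integrality = np.zeros(n_vars)
    integrality[:m] = 1
    model = _Milp(n_vars, integrality)
    c = np.zeros(n_vars)
    for (i, j), idx in v_index.items():
        c[idx] = problem.t[i][j] * problem.b[j]
    for j in problem.demand_points:  # (15)
        row = np.zeros(n_vars)
        for i in stationed:
            row[v_index[(i, j)]] = 1.0
        model.add(row, 1.0, 1.0)
    for (i, j), idx in v_index.items():  # (16)
        row = np.zeros(n_vars)
        row[idx] = 1.0
        row[stationed.index(i)] = -1.0
        model.add(row, -np.inf, 0.0)
    row = np.zeros(n_vars)  # (18)
    row[:m] = 1.0
    model.add(row, float(problem.r), float(problem.r))
    tie = np.zeros(n_vars)
    tie[:m] = 1.0 + np.arange(m)
    res = model.solve_canonical(c, tie, time_limit)
    _check(res, "hierarchical upper level")
    als_sites = tuple(i for idx, i in enumerate(stationed) if round(res.x[idx]))
    order = {i: idx for idx, i in enumerate(problem.sites)}
    als_assignment = {
        j: min(als_sites, key=lambda i: (problem.t[i][j], order[i]))
        for j in problem.demand_points
    }
    g_als = sum(
        problem.t[i][j] * problem.b[j] for j, i in als_assignment.items()
    )
    sol.als_sites = als_sites
    sol.als_assignment = als_assignment
    sol.g_als = g_als
    sol.meta["model"] = "hierarchical"
    return sol


# ---------------------------------------------------------------------------
# Kernel search


@dataclass(frozen=True)
class KernelSearchParams:
    bucket_size: int | None = None  # default: 2 * |kernel|
    max_passes: int = 3
    subproblem_time_limit: float | None = None


def kernel_search(
    problem: LocationProblem,
    params: KernelSearchParams = KernelSearchParams(),
    coverage_floor: float | None = None,
) -> LocationSolution:
    """Kernel-search matheuristic for the weighted p-median.

    The kernel is seeded from the LP relaxation (sites with positive
    fractional value); remaining sites are sorted by LP reduced cost into
    buckets.  Each pass solves restricted MILPs over kernel + one bucket,
    absorbing variables that enter an improved incumbent.  Stops after a
    full pass without improvement or ``max_passes``.
    """
    model, c, opens = _pmedian_milp(problem, coverage_floor)
    lp = model.solve_lp(c)
    if lp.status != 0:
        raise InfeasibleProblemError(f"LP relaxation failed: {lp.message}")
    m = len(opens)
    values = lp.x[:m]
    reduced = lp.lower.marginals[:m] if lp.lower is not None else np.zeros(m)

    kernel = [idx for idx in range(m) if values[idx] > 1e-6]
    outside = sorted(
        (idx for idx in range(m) if idx not in set(kernel)),
        key=lambda idx: (reduced[idx], idx),
    )
    while len(kernel) < problem.p_new and outside:
        kernel.append(outside.pop(0))

    bucket_size = params.bucket_size or max(1, 2 * len(kernel))
    buckets = [
        outside[s : s + bucket_size] for s in range(0, len(outside), bucket_size)
    ]

    def restricted_solve(allowed: set[int]):
        fix_rows = []
        for idx in range(m):
            if idx not in allowed:
                row = np.zeros(model.n)
                row[idx] = 1.0
                fix_rows.append(row)
        for row in fix_rows:
            model.add(row, 0.0, 0.0)
        tie = np.zeros(model.n)
        tie[:m] = 1.0 + np.arange(m)
        res = model.solve_canonical(c, tie, params.subproblem_time_limit)
        for _ in fix_rows:
            model.rows.pop(), model.lbs.pop(), model.ubs.pop()
        return res

    incumbent = restricted_solve(set(kernel))
    bi = 0
    while incumbent.status != 0 and bi < len(buckets):
        kernel += buckets[bi]
        bi += 1
        incumbent = restricted_solve(set(kernel))
    buckets = buckets[bi:]
    if incumbent.status != 0:
        raise InfeasibleProblemError(
            "kernel search found no feasible restricted problem"
        )
    best_val = float(c @ incumbent.x)
    best_x = incumbent.x

    for _ in range(params.max_passes):
        improved = False
        for bucket in buckets:
            if not bucket:
                continue
            res = restricted_solve(set(kernel) | set(bucket))
            if res.status == 0 and float(c @ res.x) < best_val - _TIE_TOL:
                best_val = float(c @ res.x)
                best_x = res.x
                entered = [idx for idx in bucket if res.x[idx] > 0.5]
                kernel += entered
                improved = True
        if not improved:
            break

    x = {i: 0 for i in problem.sites}
    for idx, i in enumerate(opens):
        x[i] = int(round(best_x[idx]))
    assignment = _nearest_assignment(problem, _servers(problem, x))
    return LocationSolution(
        x=x,
        assignment=assignment,
        f=expected_coverage(x, problem),
        g=total_weighted_time(assignment, problem),
        meta={"model": "pmp", "method": "kernel_search", "coverage_floor": coverage_floor},
    )


# ---------------------------------------------------------------------------
# Post-processing


def allocate_als_posthoc(
    solution: LocationSolution,
    problem: LocationProblem,
    current_stations: Mapping,
    current_als: Mapping,
    r: int | None = None,
) -> dict:
    """Assign ALS/BLS types to sited stations after a type-blind solve.

    Rules, in order: stations that did not move (fixed or re-selected at a
    site that has a station today) keep their current type; current ALS
    sites that lost their station are matched greedily, in increasing
    travel time, to the nearest still-untyped new stations; everything else
    becomes BLS.  The result is adjusted to exactly ``r`` ALS units.

    Returns site -> (stations, als) over all sited stations.
    """
    r = problem.r if r is None else r
    sited: dict = {}
    for i in problem.sites:
        cnt = problem.st.get(i, 0) + int(solution.x.get(i, 0))
        if cnt > 0:
            sited[i] = cnt
    total = sum(sited.values())
    if r > total:
        raise ValueError(f"r={r} exceeds the {total} sited stations")

    order = {i: idx for idx, i in enumerate(problem.sites)}
    als: dict = {i: 0 for i in sited}
    # rule 1: unmoved stations keep their type
    for i in sited:
        if current_stations.get(i, 0) > 0:
            als[i] = min(current_als.get(i, 0), sited[i])
    # rule 2: displaced ALS matched greedily to nearest untyped new stations
    displaced = []
    for i, n_als in current_als.items():
        lost = n_als - (als.get(i, 0) if i in sited else 0)
        displaced += [i] * max(0, lost)
    candidates = [
        i for i in sited if current_stations.get(i, 0) == 0 and als[i] < sited[i]
    ]
    edges = sorted(
        (
            (problem.t[src][dst], order[dst], src, dst)
            for src in set(displaced)
            for dst in candidates
        ),
    )
    need = {i: displaced.count(i) for i in set(displaced)}
    free = {i: sited[i] - als[i] for i in candidates}
    for _, _, src, dst in edges:
        if need.get(src, 0) > 0 and free.get(dst, 0) > 0:
            als[dst] += 1
            need[src] -= 1
            free[dst] -= 1
    # rule 3 + exact-count adjustment
    current = sum(als.values())
    sites_sorted = sorted(sited, key=lambda i: order[i])
    while current < r:
        grew = False
        for i in sites_sorted:
            if als[i] < sited[i]:
                als[i] += 1
                current += 1
                grew = True
                break
        if not grew:  # pragma: no cover - r <= total guarantees progress
            break
    while current > r:
        for i in reversed(sites_sorted):
            if als[i] > 0:
                als[i] -= 1
                current -= 1
                break
    return {i: (sited[i], als[i]) for i in sited}


def total_weighted_time(assignment: Mapping, problem: LocationProblem) -> float:
    """``g = sum_j t[i_j][j] * b_j`` for a complete assignment."""
    missing = [j for j in problem.demand_points if j not in assignment]
    if missing:
        raise ValueError(f"unassigned demand points: {missing!r}")
    return sum(
        problem.t[assignment[j]][j] * problem.b[j] for j in problem.demand_points
    )
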