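"""Independent brute-force oracles for the location models.

Everything here enumerates subsets directly and never touches the MILP
code paths under test.
"""

import itertools
import math

_FLOOR_SLACK = 1e-6


def coverage_value(problem, open_set):
    """Expected covered high-priority demand of a station subset."""
    f = 0.0
    for j in problem.demand_points:
        nj = [i for i in problem.sites if problem.t[i][j] <= problem.T_max]
        m = sum(problem.st.get(i, 0) for i in nj) + sum(1 for i in nj if i in open_set)
        m = min(m, len(nj))
        qj = problem.q.get(j, 0.0)
        f += problem.b_fhq[j] * (1.0 - qj**m)
    return f


def median_value(problem, open_set):
    """Total demand-weighted travel time under nearest assignment."""
    servers = set(open_set) | set(problem.I1)
    g = 0.0
    for j in problem.demand_points:
        g += problem.b[j] * min(problem.t[i][j] for i in servers)
    return g


def _subsets(problem):
    opens = [i for i in problem.sites if problem.st.get(i, 0) == 0]
    return itertools.combinations(opens, problem.p - sum(problem.st.values()))


def brute_mexclp(problem):
    best = None
    for subset in _subsets(problem):
        f = coverage_value(problem, subset)
        if best is None or f > best[0] + 1e-12:
            best = (f, subset)
    return best


def brute_pmedian(problem, coverage_floor=None):
    best = None
    for subset in _subsets(problem):
        if coverage_floor is not None:
            if coverage_value(problem, subset) < coverage_floor * (1 - _FLOOR_SLACK):
                continue
        g = median_value(problem, subset)
        if best is None or g < best[0] - 1e-12:
            best = (g, subset)
    return best


def brute_lexicographic(problem):
    f_star, _ = brute_mexclp(problem)
    g, subset = brute_pmedian(problem, coverage_floor=f_star)
    return f_star, g, subset


def brute_upper(problem, stationed, r):
    """Best ALS placement (value, subset) among a given station set."""
    best = None
    for als in itertools.combinations(sorted(stationed), r):
        g_als = sum(
            problem.b[j] * min(problem.t[i][j] for i in als)
            for j in problem.demand_points
        )
        if best is None or g_als < best[0] - 1e-12:
            best = (g_als, als)
    return best


def brute_hierarchical(problem):
    g, subset = brute_pmedian(problem)
    stationed = sorted(set(subset) | {i for i in problem.sites if problem.st.get(i, 0)})
    best = None
    for als in itertools.combinations(stationed, problem.r):
        g_als = sum(
            problem.b[j] * min(problem.t[i][j] for i in als)
            for j in problem.demand_points
        )
        if best is None or g_als < best[0] - 1e-12:
            best = (g_als, als)
    return g, best[0], subset, best[1]
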