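import networkx as nx
import numpy as np
import pytest

from emsloc.fixtures import GridCell, Hospital, Municipality, Region, RegionSpec, generate_region
from emsloc.optimize import LocationProblem


@pytest.fixture(scope="session")
def small_region():
    return generate_region(
        RegionSpec(n_municipalities=12, n_current_stations=4, n_hospitals=2, seed=7)
    )


@pytest.fixture(scope="session")
def medium_region():
    return generate_region(
        RegionSpec(n_municipalities=20, n_current_stations=6, n_hospitals=3, seed=11)
    )


def make_line_region(
    edge_minutes=(5.0, 5.0),
    stations=None,
    hospitals=None,
    category="local",
    urban=False,
):
    """Hand-built line region: nodes 0..n on a path with exact edge lengths.

    ``edge_minutes`` are desired lights-and-sirens off-peak traversal times;
    lengths are back-computed from the tabulated speed so travel times in
    tests are exact by construction.
    """
    from emsloc.travel import speed_lookup

    speed = speed_lookup(category, urban, "lights_sirens", "offpeak")
    g = nx.Graph()
    n = len(edge_minutes) + 1
    for i in range(n):
        g.add_node(i, x=float(i), y=0.0)
    for i, minutes in enumerate(edge_minutes):
        g.add_edge(
            i,
            i + 1,
            length_km=minutes * speed / 60.0,
            category=category,
            urban=urban,
        )
    munis = []
    stations = stations or {}
    for i in range(n):
        cnt, als = stations.get(i, (0, 0))
        munis.append(
            Municipality(
                id=i,
                name=f"m{i}",
                node_id=i,
                pop_0_14=100,
                pop_15_64=700,
                pop_65plus=200,
                current_stations=cnt,
                current_als=als,
            )
        )
    hosp = [
        Hospital(
            id=k,
            node_id=node,
            specializations=frozenset({"general"}),
            dropoff_shape=3,
            dropoff_mean=10.0,
        )
        for k, node in enumerate(hospitals or [])
    ]
    grid = [
        GridCell(id=f"c{i}", municipality_id=i, node_id=i, weight=1000.0)
        for i in range(n)
    ]
    return Region(municipalities=munis, network=g, hospitals=hosp, grid=grid)


def random_problem(rng, n_sites=None, p=None, with_fixed=False):
    """Random small LocationProblem for oracle-equivalence tests."""
    n = n_sites or int(rng.integers(4, 11))
    sites = tuple(range(n))
    t = {
        i: {j: 0.0 if i == j else float(rng.uniform(1.0, 20.0)) for j in sites}
        for i in sites
    }
    for i in sites:  # symmetrize
        for j in sites:
            t[i][j] = t[j][i] = min(t[i][j], t[j][i])
    b = {j: float(rng.uniform(1.0, 100.0)) for j in sites}
    b_fhq = {j: b[j] * float(rng.uniform(0.1, 0.5)) for j in sites}
    q = {j: float(rng.uniform(0.0, 0.8)) for j in sites}
    st: dict = {}
    I1 = frozenset()
    extra_fixed = 0
    if with_fixed and n >= 5:
        fixed_site = int(rng.integers(0, n))
        st = {fixed_site: 1}
        extra_fixed = 1
        if rng.random() < 0.5:
            I1 = frozenset({fixed_site})
    p = p if p is not None else int(rng.integers(1, 5))
    p = min(p, n - extra_fixed) + extra_fixed
    r = int(rng.integers(1, p + 1))
    return LocationProblem(
        sites=sites,
        demand_points=sites,
        t=t,
        b=b,
        b_fhq=b_fhq,
        q=q,
        p=p,
        r=r,
        st=st,
        I1=I1,
        T_max=float(rng.uniform(4.0, 12.0)),
    )
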