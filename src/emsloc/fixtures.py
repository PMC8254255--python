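"""Seeded synthetic regions and deterministic call scripts.

Stands in for real census, road-network and ambient-population inputs: a
:class:`RegionSpec` fully determines (via its seed) a connected road
network with mixed road categories, age-structured municipal populations,
current stations (ALS/BLS), hospitals with Erlang drop-off parameters and
a population grid used for call placement.  Regions round-trip losslessly
through a directory of CSV/GraphML/JSON files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from emsloc.travel import ROAD_CATEGORIES

__all__ = [
    "RegionSpec",
    "Municipality",
    "Hospital",
    "GridCell",
    "Region",
    "ScriptedCall",
    "generate_region",
    "write_region",
    "read_region",
    "generate_call_script",
]

HOSPITAL_SPECIALIZATIONS = ("general", "pediatric", "cardio")
DROPOFF_MEAN_RANGE = (7.1, 36.2)  # minutes

# sampling weights for edge road categories
_URBAN_CATEGORY_WEIGHTS = {
    "local": 0.40,
    "residential": 0.20,
    "national": 0.20,
    "important_national": 0.10,
    "expressway": 0.05,
    "motorway": 0.05,
}
_RURAL_CATEGORY_WEIGHTS = {
    "national": 0.30,
    "local": 0.25,
    "important_national": 0.15,
    "minor": 0.15,
    "expressway": 0.08,
    "motorway": 0.07,
}


@dataclass(frozen=True)
class RegionSpec:
    """Parameters of a synthetic region; the seed fully determines output."""

    n_municipalities: int = 20
    urban_fraction: float = 0.3
    age_structure_params: tuple[tuple[float, float], tuple[float, float]] = (
        (0.12, 0.20),  # share of 0-14
        (0.08, 0.28),  # share of 65+
    )
    n_hospitals: int = 2
    n_current_stations: int = 5
    als_fraction: float = 0.33
    grid_resolution: int = 2  # cells per municipality
    network_style: str = "grid"
    seed: int = 0
    max_stations_per_town: int = 4

    def validate(self) -> None:
        if self.n_municipalities < 1:
            raise ValueError("n_municipalities must be >= 1")
        for name in ("urban_fraction", "als_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_hospitals < 0:
            raise ValueError("n_hospitals must be >= 0")
        if self.n_current_stations < 0:
            raise ValueError("n_current_stations must be >= 0")
        if self.n_current_stations > self.n_municipalities * self.max_stations_per_town:
            raise ValueError(
                "n_current_stations exceeds n_municipalities * max_stations_per_town"
            )
        if self.grid_resolution < 1:
            raise ValueError("grid_resolution must be >= 1")
        if self.network_style not in ("grid", "random-geometric"):
            raise ValueError(f"unknown network_style {self.network_style!r}")
        lo0, hi0 = self.age_structure_params[0]
        lo2, hi2 = self.age_structure_params[1]
        if not (0 <= lo0 <= hi0 <= 1 and 0 <= lo2 <= hi2 <= 1 and hi0 + hi2 < 1):
            raise ValueError("age share ranges must be valid proportions summing < 1")


@dataclass(frozen=True)
class Municipality:
    id: int
    name: str
    node_id: int
    pop_0_14: int
    pop_15_64: int
    pop_65plus: int
    current_stations: int = 0
    current_als: int = 0

    @property
    def population(self) -> int:
        return self.pop_0_14 + self.pop_15_64 + self.pop_65plus

    @property
    def pop_kj(self) -> tuple[int, int, int]:
        return (self.pop_0_14, self.pop_15_64, self.pop_65plus)


@dataclass(frozen=True)
class Hospital:
    id: int
    node_id: int
    specializations: frozenset[str]
    dropoff_shape: int
    dropoff_mean: float

    def __post_init__(self) -> None:
        if self.dropoff_shape < 1 or int(self.dropoff_shape) != self.dropoff_shape:
            raise ValueError("dropoff_shape must be an integer >= 1")
        unknown = set(self.specializations) - set(HOSPITAL_SPECIALIZATIONS)
        if unknown:
            raise ValueError(f"unknown specializations: {sorted(unknown)}")


@dataclass(frozen=True)
class GridCell:
    id: str
    municipality_id: int
    node_id: int
    weight: float


@dataclass
class Region:
    municipalities: list[Municipality]
    network: nx.Graph
    hospitals: list[Hospital]
    grid: list[GridCell]
    spec: RegionSpec | None = None

    def municipality_by_id(self, mid: int) -> Municipality:
        return next(m for m in self.municipalities if m.id == mid)

    @property
    def station_nodes(self) -> dict[int, tuple[int, int]]:
        """node -> (stations, als) for municipalities hosting stations."""
        return {
            m.node_id: (m.current_stations, m.current_als)
            for m in self.municipalities
            if m.current_stations > 0
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Region):
            return NotImplemented
        same_graph = (
            set(self.network.nodes) == set(other.network.nodes)
            and dict(self.network.nodes(data=True)) == dict(other.network.nodes(data=True))
            and nx.utils.graphs_equal(self.network, other.network)
        )
        return (
            self.municipalities == other.municipalities
            and self.hospitals == other.hospitals
            and self.grid == other.grid
            and same_graph
        )


def _lattice_positions(n: int, rng: np.random.Generator) -> list[tuple[float, float]]:
    cols = math.ceil(math.sqrt(n))
    spacing = 6.0  # km between neighbouring town centres
    pos = []
    for i in range(n):
        r, c = divmod(i, cols)
        jitter = rng.uniform(-1.0, 1.0, size=2)
        pos.append((c * spacing + jitter[0], r * spacing + jitter[1]))
    return pos


def _sample_category(urban: bool, rng: np.random.Generator) -> str:
    weights = _URBAN_CATEGORY_WEIGHTS if urban else _RURAL_CATEGORY_WEIGHTS
    cats = list(weights)
    p = np.array([weights[c] for c in cats])
    return cats[rng.choice(len(cats), p=p / p.sum())]


def _build_network(
    spec: RegionSpec, urban: np.ndarray, rng: np.random.Generator
) -> nx.Graph:
    n = spec.n_municipalities
    g = nx.Graph()
    pos = _lattice_positions(n, rng)
    for i in range(n):
        g.add_node(i, x=float(pos[i][0]), y=float(pos[i][1]))

    def euclid(a: int, b: int) -> float:
        (xa, ya), (xb, yb) = pos[a], pos[b]
        return math.hypot(xa - xb, ya - yb)

    pairs: set[tuple[int, int]] = set()
    if spec.network_style == "grid":
        cols = math.ceil(math.sqrt(n))
        for i in range(n):
            r, c = divmod(i, cols)
            for j in (i + 1, i + cols):
                if j < n and (j != i + 1 or c != cols - 1):
                    pairs.add((i, j))
        # a lattice row may end up shorter than cols; stitch any leftover
        # components with nearest-neighbour edges
    else:  # random-geometric: k-nearest neighbours
        k = min(3, n - 1)
        for i in range(n):
            order = sorted((j for j in range(n) if j != i), key=lambda j: euclid(i, j))
            for j in order[:k]:
                pairs.add((min(i, j), max(i, j)))
    for a, b in sorted(pairs):
        e_urban = bool(urban[a] and urban[b])
        length = max(0.3, euclid(a, b) * rng.uniform(1.0, 1.4))
        g.add_edge(
            a,
            b,
            length_km=round(float(length), 4),
            category=_sample_category(e_urban, rng),
            urban=e_urban,
        )
    while not nx.is_connected(g) and n > 1:
        comps = sorted(nx.connected_components(g), key=min)
        best = None
        for a in sorted(comps[0]):
            for b in sorted(set(g.nodes) - comps[0]):
                d = euclid(a, b)
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        g.add_edge(
            a,
            b,
            length_km=round(max(0.3, euclid(a, b)), 4),
            category="national",
            urban=bool(urban[a] and urban[b]),
        )
    return g


def generate_region(spec: RegionSpec) -> Region:
    """Generate a synthetic region; identical specs yield identical regions."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_municipalities

    n_urban = int(round(spec.urban_fraction * n))
    urban = np.zeros(n, dtype=bool)
    urban[rng.choice(n, size=n_urban, replace=False)] = True

    totals = np.where(
        urban,
        rng.integers(8_000, 60_000, size=n),
        rng.integers(300, 4_000, size=n),
    )
    (lo0, hi0), (lo2, hi2) = spec.age_structure_params
    share0 = rng.uniform(lo0, hi0, size=n)
    share2 = rng.uniform(lo2, hi2, size=n)
    pop0 = np.round(totals * share0).astype(int)
    pop2 = np.round(totals * share2).astype(int)
    pop1 = totals - pop0 - pop2

    network = _build_network(spec, urban, rng)

    # stations drawn town by town, probability proportional to population,
    # capped per town
    station_count = np.zeros(n, dtype=int)
    weights = totals.astype(float)
    for _ in range(spec.n_current_stations):
        w = np.where(station_count < spec.max_stations_per_town, weights, 0.0)
        if w.sum() == 0:
            break
        station_count[rng.choice(n, p=w / w.sum())] += 1
    n_als = int(round(spec.als_fraction * spec.n_current_stations))
    als_count = np.zeros(n, dtype=int)
    by_pop = sorted(range(n), key=lambda i: (-totals[i], i))
    remaining = n_als
    for i in by_pop:
        if remaining == 0:
            break
        take = min(station_count[i] - als_count[i], remaining)
        als_count[i] += take
        remaining -= take

    municipalities = [
        Municipality(
            id=i,
            name=f"{'town' if urban[i] else 'village'}-{i:03d}",
            node_id=i,
            pop_0_14=int(pop0[i]),
            pop_15_64=int(pop1[i]),
            pop_65plus=int(pop2[i]),
            current_stations=int(station_count[i]),
            current_als=int(als_count[i]),
        )
        for i in range(n)
    ]

    hosp_sites = by_pop[: spec.n_hospitals]
    hospitals = []
    for h, site in enumerate(hosp_sites):
        if h == 0:
            specs = {"general"}
        else:
            specs = {"general"} if rng.random() < 0.6 else set()
            if rng.random() < 0.4:
                specs.add("pediatric")
            if rng.random() < 0.4:
                specs.add("cardio")
            if not specs:
                specs = {"general"}
        hospitals.append(
            Hospital(
                id=h,
                node_id=int(site),
                specializations=frozenset(specs),
                dropoff_shape=3,
                dropoff_mean=round(float(rng.uniform(*DROPOFF_MEAN_RANGE)), 2),
            )
        )

    grid = []
    for m in municipalities:
        split = rng.dirichlet(np.ones(spec.grid_resolution))
        for c in range(spec.grid_resolution):
            grid.append(
                GridCell(
                    id=f"c{m.id}_{c}",
                    municipality_id=m.id,
                    node_id=m.node_id,
                    weight=round(float(m.population * split[c]), 4),
                )
            )

    return Region(
        municipalities=municipalities,
        network=network,
        hospitals=hospitals,
        grid=grid,
        spec=spec,
    )


_MUNI_COLUMNS = [
    "id",
    "name",
    "node_id",
    "pop_0_14",
    "pop_15_64",
    "pop_65plus",
    "current_stations",
    "current_als",
]


def write_region(region: Region, directory: str | Path) -> list[Path]:
    """Serialize a region to CSV/GraphML/JSON files; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    munis = pd.DataFrame(
        [
            {c: getattr(m, c) for c in _MUNI_COLUMNS}
            for m in region.municipalities
        ]
    )
    p = directory / "municipalities.csv"
    munis.to_csv(p, index=False)
    written.append(p)

    p = directory / "network.graphml"
    nx.write_graphml(region.network, p)
    written.append(p)

    hosp = pd.DataFrame(
        [
            {
                "id": h.id,
                "node_id": h.node_id,
                "specializations": ";".join(sorted(h.specializations)),
                "dropoff_shape": h.dropoff_shape,
                "dropoff_mean": h.dropoff_mean,
            }
            for h in region.hospitals
        ],
        columns=["id", "node_id", "specializations", "dropoff_shape", "dropoff_mean"],
    )
    p = directory / "hospitals.csv"
    hosp.to_csv(p, index=False)
    written.append(p)

    grid = pd.DataFrame(
        [
            {
                "cell_id": c.id,
                "municipality_id": c.municipality_id,
                "node_id": c.node_id,
                "weight": c.weight,
            }
            for c in region.grid
        ],
        columns=["cell_id", "municipality_id", "node_id", "weight"],
    )
    p = directory / "grid.csv"
    grid.to_csv(p, index=False)
    written.append(p)

    manifest = {
        "format": "emsloc-region",
        "version": 1,
        "n_municipalities": len(region.municipalities),
        "n_hospitals": len(region.hospitals),
        "n_grid_cells": len(region.grid),
        "spec": None if region.spec is None else region.spec.__dict__ | {
            "age_structure_params": [list(r) for r in region.spec.age_structure_params]
        },
    }
    p = directory / "region.json"
    p.write_text(json.dumps(manifest, indent=2) + "\n")
    written.append(p)
    return written


def read_region(directory: str | Path) -> Region:
    """Read a region written by :func:`write_region` (lossless round trip)."""
    directory = Path(directory)
    muni_path = directory / "municipalities.csv"
    if not muni_path.exists():
        raise FileNotFoundError(f"missing {muni_path}")
    munis = pd.read_csv(muni_path)
    missing = [c for c in _MUNI_COLUMNS if c not in munis.columns]
    if missing:
        raise ValueError(
            f"{muni_path}: missing required column(s) {missing}"
        )
    municipalities = [
        Municipality(
            id=int(r.id),
            name=str(r.name),
            node_id=int(r.node_id),
            pop_0_14=int(r.pop_0_14),
            pop_15_64=int(r.pop_15_64),
            pop_65plus=int(r.pop_65plus),
            current_stations=int(r.current_stations),
            current_als=int(r.current_als),
        )
        for r in munis.itertuples(index=False)
    ]

    network = nx.read_graphml(directory / "network.graphml", node_type=int)
    clean = nx.Graph()
    for node, data in network.nodes(data=True):
        clean.add_node(int(node), x=float(data["x"]), y=float(data["y"]))
    for a, b, data in network.edges(data=True):
        urban = data["urban"]
        if isinstance(urban, str):
            urban = urban.strip().lower() == "true"
        clean.add_edge(
            int(a),
            int(b),
            length_km=float(data["length_km"]),
            category=str(data["category"]),
            urban=bool(urban),
        )

    hosp_path = directory / "hospitals.csv"
    hospitals = []
    hosp = pd.read_csv(hosp_path)
    for r in hosp.itertuples(index=False):
        specs = str(r.specializations)
        hospitals.append(
            Hospital(
                id=int(r.id),
                node_id=int(r.node_id),
                specializations=frozenset(s for s in specs.split(";") if s),
                dropoff_shape=int(r.dropoff_shape),
                dropoff_mean=float(r.dropoff_mean),
            )
        )

    grid_df = pd.read_csv(directory / "grid.csv")
    grid = [
        GridCell(
            id=str(r.cell_id),
            municipality_id=int(r.municipality_id),
            node_id=int(r.node_id),
            weight=float(r.weight),
        )
        for r in grid_df.itertuples(index=False)
    ]

    spec = None
    manifest_path = directory / "region.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        raw = manifest.get("spec")
        if raw is not None:
            raw = dict(raw)
            raw["age_structure_params"] = tuple(
                tuple(r) for r in raw["age_structure_params"]
            )
            spec = RegionSpec(**raw)

    return Region(
        municipalities=municipalities,
        network=clean,
        hospitals=hospitals,
        grid=grid,
        spec=spec,
    )


@dataclass(frozen=True)
class ScriptedCall:
    """One deterministic call the simulator can consume as-is."""

    time_min: float
    node_id: int
    priority: str  # "FHQ" or "non-FHQ"
    diagnosis: str = "general"


def generate_call_script(
    events: Iterable[tuple[float, int, str]],
    nodes: Sequence[int] | None = None,
) -> list[ScriptedCall]:
    """Turn (time, node, priority) triples into a validated call script.

    Times must be nondecreasing; if ``nodes`` is given, every node must be
    a member.
    """
    script: list[ScriptedCall] = []
    last = -math.inf
    node_set = set(nodes) if nodes is not None else None
    for time_min, node_id, priority in events:
        if time_min < last:
            raise ValueError("call times must be nondecreasing")
        if node_set is not None and node_id not in node_set:
            raise ValueError(f"unknown node {node_id!r} in call script")
        if priority not in ("FHQ", "non-FHQ"):
            raise ValueError(f"unknown priority {priority!r}")
        script.append(ScriptedCall(time_min=float(time_min), node_id=node_id, priority=priority))
        last = time_min
    return script
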