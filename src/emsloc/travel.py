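"""Deterministic travel times on a categorized road network.

Per-edge times come from tabulated average ambulance speeds that depend on
the road category, urban/rural location, driving mode (lights & sirens vs
standard) and time-of-day regime (off-peak, morning rush 6:30-9:00, evening
rush 15:00-18:00).  Shortest-path times build the origin-destination matrix
``t_ij`` (minutes) and the coverage neighbourhoods ``N_j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Mode",
    "Regime",
    "ROAD_CATEGORIES",
    "SpeedModel",
    "TravelTimeMatrix",
    "Neighbourhoods",
    "speed_lookup",
    "edge_travel_time",
    "travel_time_matrix",
    "neighbourhoods",
    "regime_at",
]


class Mode(str, Enum):
    LIGHTS_SIRENS = "lights_sirens"
    STANDARD = "standard"


class Regime(str, Enum):
    OFFPEAK = "offpeak"
    MORNING_RUSH = "morning_rush"
    EVENING_RUSH = "evening_rush"


ROAD_CATEGORIES = (
    "motorway",
    "expressway",
    "important_national",
    "national",
    "local",
    "residential",
    "minor",
)

_REGIMES = (Regime.OFFPEAK, Regime.MORNING_RUSH, Regime.EVENING_RUSH)

# (category, urban) -> {mode: (offpeak, morning_rush, evening_rush)} in km/h.
# The urban residential and minor rows are not reliably known; the defaults
# below are deliberately conservative and configurable via SpeedModel.
_URBAN = {
    "motorway": {Mode.LIGHTS_SIRENS: (100, 92, 90), Mode.STANDARD: (90, 86, 86)},
    "expressway": {Mode.LIGHTS_SIRENS: (100, 92, 89), Mode.STANDARD: (90, 84, 82)},
    "important_national": {Mode.LIGHTS_SIRENS: (65, 60, 56), Mode.STANDARD: (46, 42, 40)},
    "national": {Mode.LIGHTS_SIRENS: (60, 51, 55), Mode.STANDARD: (40, 39, 38)},
    "local": {Mode.LIGHTS_SIRENS: (59, 50, 50), Mode.STANDARD: (36, 35, 35)},
    "residential": {Mode.LIGHTS_SIRENS: (30, 28, 28), Mode.STANDARD: (25, 24, 24)},
    "minor": {Mode.LIGHTS_SIRENS: (25, 25, 25), Mode.STANDARD: (20, 20, 20)},
}
_RURAL = {
    "motorway": {Mode.LIGHTS_SIRENS: (110, 100, 102), Mode.STANDARD: (100, 100, 100)},
    "expressway": {Mode.LIGHTS_SIRENS: (110, 98, 98), Mode.STANDARD: (100, 90, 90)},
    "important_national": {Mode.LIGHTS_SIRENS: (101, 88, 89), Mode.STANDARD: (86, 67, 65)},
    "national": {Mode.LIGHTS_SIRENS: (91, 78, 80), Mode.STANDARD: (67, 58, 57)},
    "local": {Mode.LIGHTS_SIRENS: (68, 59, 60), Mode.STANDARD: (58, 53, 55)},
    "residential": {Mode.LIGHTS_SIRENS: (40, 38, 38), Mode.STANDARD: (35, 34, 34)},
    "minor": {Mode.LIGHTS_SIRENS: (55, 55, 55), Mode.STANDARD: (55, 55, 55)},
}

MORNING_RUSH_WINDOW = (6.5, 9.0)  # hours of day
EVENING_RUSH_WINDOW = (15.0, 18.0)


def regime_at(hour_of_day: float) -> Regime:
    """Speed regime in force at a given clock hour (0-24)."""
    h = hour_of_day % 24.0
    if MORNING_RUSH_WINDOW[0] <= h < MORNING_RUSH_WINDOW[1]:
        return Regime.MORNING_RUSH
    if EVENING_RUSH_WINDOW[0] <= h < EVENING_RUSH_WINDOW[1]:
        return Regime.EVENING_RUSH
    return Regime.OFFPEAK


@dataclass(frozen=True)
class SpeedModel:
    """Average-speed table keyed by (category, urban, mode, regime).

    ``overrides`` replaces individual table entries; keys are
    ``(category, urban, mode, regime)`` tuples and values km/h.
    """

    overrides: Mapping[tuple, float] = field(default_factory=dict)

    def speed(self, category: str, urban: bool, mode: Mode, regime: Regime) -> float:
        key = (category, bool(urban), Mode(mode), Regime(regime))
        if key in self.overrides:
            v = float(self.overrides[key])
            if v <= 0:
                raise ValueError(f"override speed for {key} must be > 0")
            return v
        table = _URBAN if urban else _RURAL
        try:
            row = table[category][Mode(mode)]
        except KeyError:
            raise KeyError(
                f"no speed tabulated for (category={category!r}, urban={urban}, "
                f"mode={mode!r})"
            ) from None
        return float(row[_REGIMES.index(Regime(regime))])


DEFAULT_SPEED_MODEL = SpeedModel()


def speed_lookup(
    category: str,
    urban: bool,
    mode: Mode | str,
    regime: Regime | str,
    model: SpeedModel = DEFAULT_SPEED_MODEL,
) -> float:
    """Tabulated average speed in km/h."""
    return model.speed(category, urban, Mode(mode), Regime(regime))


def edge_travel_time(
    length_km: float,
    category: str,
    urban: bool,
    mode: Mode | str,
    regime: Regime | str,
    model: SpeedModel = DEFAULT_SPEED_MODEL,
) -> float:
    """Traversal time of one edge in minutes: 60 * length / speed."""
    if length_km <= 0:
        raise ValueError(f"edge length must be > 0, got {length_km}")
    return 60.0 * length_km / speed_lookup(category, urban, mode, regime, model)


def _weighted(
    network: nx.Graph, mode: Mode, regime: Regime, model: SpeedModel
) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for a, b, data in network.edges(data=True):
        minutes = edge_travel_time(
            data["length_km"], data["category"], data["urban"], mode, regime, model
        )
        g.add_edge(a, b, minutes=minutes)
    return g


@dataclass(frozen=True)
class TravelTimeMatrix:
    """Shortest-path travel times in minutes between node sets.

    ``times[i][j]`` maps origin node -> destination node -> minutes;
    unreachable pairs are ``inf``.
    """

    origins: tuple
    destinations: tuple
    times: Mapping
    mode: Mode
    regime: Regime

    def __getitem__(self, key: tuple) -> float:
        i, j = key
        return self.times[i][j]

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.times[i][j] for j in self.destinations] for i in self.origins]
        )


def travel_time_matrix(
    network: nx.Graph,
    origins: Sequence | None = None,
    destinations: Sequence | None = None,
    mode: Mode | str = Mode.LIGHTS_SIRENS,
    regime: Regime | str = Regime.OFFPEAK,
    model: SpeedModel = DEFAULT_SPEED_MODEL,
) -> TravelTimeMatrix:
    """All shortest-path times from ``origins`` to ``destinations``.

    Defaults to all network nodes on both axes.  Disconnected pairs get
    ``inf``.  Times are symmetric because the network is undirected.
    """
    nodes = list(network.nodes)
    origins = list(origins) if origins is not None else nodes
    destinations = list(destinations) if destinations is not None else nodes
    missing = [n for n in set(origins) | set(destinations) if n not in network]
    if missing:
        raise ValueError(f"nodes not in network: {sorted(missing)!r}")
    g = _weighted(network, Mode(mode), Regime(regime), model)
    dest_set = set(destinations)
    times: dict = {}
    for o in origins:
        dist = nx.single_source_dijkstra_path_length(g, o, weight="minutes")
        times[o] = {d: dist.get(d, float("inf")) for d in dest_set}
    return TravelTimeMatrix(
        origins=tuple(origins),
        destinations=tuple(destinations),
        times=times,
        mode=Mode(mode),
        regime=Regime(regime),
    )


@dataclass(frozen=True)
class Neighbourhoods:
    """Coverage neighbourhoods: candidate sites within ``T_max`` minutes."""

    T_max: float
    N_j: Mapping
    # n_j = |N_j| per demand point

    def n_j(self, j) -> int:
        return len(self.N_j[j])


def neighbourhoods(matrix: TravelTimeMatrix, T_max: float = 7.0) -> Neighbourhoods:
    """``N_j = {i : t_ij <= T_max}`` for every destination j (closed bound)."""
    if T_max < 0:
        raise ValueError(f"T_max must be >= 0, got {T_max}")
    nj = {
        j: frozenset(i for i in matrix.origins if matrix.times[i][j] <= T_max)
        for j in matrix.destinations
    }
    return Neighbourhoods(T_max=T_max, N_j=nj)
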