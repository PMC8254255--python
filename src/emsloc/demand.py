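"""Annual EMS demand estimation from age-group incident rates.

Municipal demand is the sum over three age groups (0-14, 15-64, 65+) of the
group's incident rate (annual cases per 1,000 persons) times the group's
population.  High-priority (FHQ) demand uses per-group FHQ shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AGE_GROUPS",
    "DEFAULT_RATES",
    "DEFAULT_FHQ_SHARE",
    "RateEstimationInputs",
    "AgeGroupRates",
    "compute_incident_rates",
    "estimate_annual_demand",
    "aging_index",
    "demand_table",
]

AGE_GROUPS = ("0-14", "15-64", "65+")

#: Annual emergency cases per 1,000 persons for the three age groups.
DEFAULT_RATES = (26.09, 69.12, 267.07)

#: Overall share of high-priority (FHQ) patients among all patients.
DEFAULT_FHQ_SHARE = 0.2651


@dataclass(frozen=True)
class RateEstimationInputs:
    """Inputs needed to derive per-age incident rates from a trip sample.

    ``D`` is the total annual dispatch count in the region; ``falck_k`` the
    per-age patient counts in the sample; ``pop_k`` the regional population
    per age group.
    """

    D: float
    falck_k: Sequence[float]
    falck_total: float
    pop_k: Sequence[float]

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if any(f < 0 for f in self.falck_k):
            raise ValueError("sample counts must be >= 0")
        if abs(sum(self.falck_k) - self.falck_total) > 1e-9 * max(1.0, self.falck_total):
            raise ValueError("falck_total must equal the sum of falck_k")
        if any(p <= 0 for p in self.pop_k):
            raise ValueError("pop_k must be > 0 for every age group")


@dataclass(frozen=True)
class AgeGroupRates:
    """Per-age incident rates (cases per 1,000 persons) and FHQ shares."""

    rate_k: tuple[float, ...] = DEFAULT_RATES
    fhq_share_k: tuple[float, ...] = (DEFAULT_FHQ_SHARE,) * 3

    def __post_init__(self) -> None:
        if len(self.rate_k) != len(self.fhq_share_k):
            raise ValueError("rate_k and fhq_share_k must have equal length")
        if any(r < 0 for r in self.rate_k):
            raise ValueError("rates must be >= 0")
        if any(not 0.0 <= s <= 1.0 for s in self.fhq_share_k):
            raise ValueError("FHQ shares must lie in [0, 1]")


def compute_incident_rates(
    inputs: RateEstimationInputs,
    fhq_share_k: Sequence[float] | None = None,
) -> AgeGroupRates:
    """Annual incident rate per 1,000 persons for each age group.

    ``rate_k = 1000 * D * falck_k / (pop_k * falck_total)``.
    """
    if inputs.falck_total == 0:
        raise ZeroDivisionError("sample total is zero; rates are undefined")
    rates = tuple(
        1000.0 * inputs.D * fk / (pk * inputs.falck_total)
        for fk, pk in zip(inputs.falck_k, inputs.pop_k)
    )
    shares = (
        tuple(fhq_share_k)
        if fhq_share_k is not None
        else (DEFAULT_FHQ_SHARE,) * len(rates)
    )
    return AgeGroupRates(rate_k=rates, fhq_share_k=shares)


def estimate_annual_demand(
    pop_kj: Sequence[float], rates: AgeGroupRates
) -> tuple[float, float]:
    """Annual total and FHQ patient counts for one municipality.

    Parameters
    ----------
    pop_kj:
        Population per age group, in persons.
    rates:
        Per-1,000 incident rates and FHQ shares.

    Returns
    -------
    (b_j, b_fhq_j):
        ``b_j = sum_k rate_k * pop_kj / 1000`` and the FHQ analogue with the
        per-group share applied.
    """
    if len(pop_kj) != len(rates.rate_k):
        raise ValueError("population vector length must match the number of age groups")
    if any(p < 0 for p in pop_kj):
        raise ValueError("populations must be >= 0")
    b = sum(r * p / 1000.0 for r, p in zip(rates.rate_k, pop_kj))
    b_fhq = sum(
        s * r * p / 1000.0 for s, r, p in zip(rates.fhq_share_k, rates.rate_k, pop_kj)
    )
    return b, b_fhq


def aging_index(pop_65plus: float, pop_under65: float) -> float:
    """Ratio of inhabitants aged 65+ to inhabitants below 65."""
    if pop_under65 <= 0:
        raise ZeroDivisionError("aging index undefined for zero population under 65")
    return pop_65plus / pop_under65


def demand_table(
    municipalities: pd.DataFrame, rates: AgeGroupRates | None = None
) -> pd.DataFrame:
    """Per-municipality demand frame: id, b_j, b_fhq_j, aging_index.

    ``municipalities`` must carry columns ``id``, ``pop_0_14``, ``pop_15_64``
    and ``pop_65plus`` (the dialect written by :mod:`emsloc.fixtures`).
    """
    rates = rates or AgeGroupRates()
    rows = []
    for rec in municipalities.itertuples(index=False):
        pops = (rec.pop_0_14, rec.pop_15_64, rec.pop_65plus)
        b, b_fhq = estimate_annual_demand(pops, rates)
        under65 = rec.pop_0_14 + rec.pop_15_64
        idx = aging_index(rec.pop_65plus, under65) if under65 > 0 else np.nan
        rows.append({"id": rec.id, "b_j": b, "b_fhq_j": b_fhq, "aging_index": idx})
    return pd.DataFrame(rows)
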