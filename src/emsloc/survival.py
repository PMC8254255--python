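"""Logistic survival probability as a function of EMS response time.

The model translates a reduction of the average response time into a gain
in survival probability (percentage points) and an expected number of
additional survivors in a patient cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SurvivalModel",
    "survival_probability",
    "survival_gain",
    "expected_additional_survivors",
]


@dataclass(frozen=True)
class SurvivalModel:
    """Coefficients of the logistic survival curve s(t) = 1/(1+exp(b0+b1*t)).

    ``t`` is the response time in minutes.  With ``beta1 > 0`` the curve is
    strictly decreasing: slower responses mean lower survival odds.
    """

    beta0: float = -2.04492
    beta1: float = 0.045427  # per minute

    def __post_init__(self) -> None:
        if self.beta1 < 0:
            raise ValueError("beta1 must be >= 0 for a decreasing survival curve")


DEFAULT_MODEL = SurvivalModel()


def survival_probability(t: float, model: SurvivalModel = DEFAULT_MODEL) -> float:
    """Survival probability for a response time of ``t`` minutes.

    Parameters
    ----------
    t:
        Response time in minutes; must be non-negative.
    model:
        Logistic coefficients.

    Returns
    -------
    float
        ``1 / (1 + exp(beta0 + beta1 * t))``, always in (0, 1).
    """
    if t < 0:
        raise ValueError(f"response time must be >= 0, got {t}")
    return 1.0 / (1.0 + math.exp(model.beta0 + model.beta1 * t))


def survival_gain(
    t0: float, reduction_s: float, model: SurvivalModel = DEFAULT_MODEL
) -> float:
    """Survival-probability gain, in percentage points, from a response-time cut.

    Parameters
    ----------
    t0:
        Baseline average response time in minutes.
    reduction_s:
        Reduction of the response time in **seconds** (non-negative and at
        most ``60 * t0``).

    Returns
    -------
    float
        ``100 * (s(t0 - reduction_s/60) - s(t0))``.
    """
    if reduction_s < 0:
        raise ValueError(f"reduction must be >= 0, got {reduction_s}")
    if reduction_s > 60.0 * t0:
        raise ValueError(
            f"reduction of {reduction_s} s exceeds the baseline time of {t0} min"
        )
    t1 = t0 - reduction_s / 60.0
    return 100.0 * (survival_probability(t1, model) - survival_probability(t0, model))


def expected_additional_survivors(
    n_patients: float,
    t0: float,
    reduction_s: float,
    model: SurvivalModel = DEFAULT_MODEL,
) -> float:
    """Expected additional survivors among ``n_patients`` critical patients.

    Linear in the cohort size: ``n_patients * survival_gain / 100``.
    """
    if n_patients < 0:
        raise ValueError(f"patient count must be >= 0, got {n_patients}")
    return n_patients * survival_gain(t0, reduction_s, model) / 100.0
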