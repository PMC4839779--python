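"""Expenditure, budget impact and the inverse budget-cap problem.

Total expenditure for treating ``n`` patients under the decay model is the
area under the price-volume curve,

    total(n) = integral_0^n fPRICE * exp(-k x) dx
             = fPRICE * (1 - exp(-k n)) / k          (k > 0)
             = fPRICE * n                            (k = 0)

available both in this closed form and by the composite trapezoidal rule on
the curve (the traditional AUC computation; an upper bound, since the
integrand is convex).  Dividing by ``n`` gives the average cost per patient,
which also has the closed form (fPRICE - PRICE_last) / (k * n) with
PRICE_last the price at ``n`` — algebraically identical to total/n.

The nationwide budget impact (NWBI) is the undiscounted worst case:
full price times the whole candidate population, with no decay applied.

The inverse problem — given a full price, a candidate population and an
affordable budget, how fast must the price decay? — is solved by bracketed
root-finding on ``k`` (total expenditure is strictly decreasing in ``k``, so
the root is unique).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .model import (
    HALF_LIFE_CONST,
    DomainError,
    PriceVolumeModel,
    price_at,
)

__all__ = [
    "ExpenditureMethod",
    "ExpenditureSummary",
    "Agreement",
    "nwbi",
    "total_expenditure_analytic",
    "total_expenditure_trapezoid",
    "average_cost_closed_form",
    "solve_decay_for_budget",
    "tier_schedule",
]


class ExpenditureMethod(str, Enum):
    ANALYTIC = "analytic"
    TRAPEZOID = "trapezoid"


@dataclass(frozen=True)
class ExpenditureSummary:
    """Total expenditure and average cost over ``n_patients`` treated.

    ``total == average_per_patient * n_patients`` by construction;
    ``step`` is set only for the trapezoidal method.
    """

    total: float  # EUR
    average_per_patient: float  # EUR
    n_patients: float
    method: ExpenditureMethod
    step: float | None = None


@dataclass(frozen=True)
class Agreement:
    """A named drug scenario: fitted model plus candidate population.

    ``tot_pt`` is the total number of patients who are candidates for the
    treatment nationwide; ``nwbi`` (full price x tot_pt) is derived.
    """

    drug: str
    model: PriceVolumeModel
    tot_pt: float

    def __post_init__(self) -> None:
        if self.tot_pt <= 0:
            raise DomainError(f"tot_pt must be positive, got {self.tot_pt!r}")

    @property
    def nwbi(self) -> float:
        return nwbi(self.model.f_price, self.tot_pt)

    @property
    def php(self) -> float:
        return self.model.php


def nwbi(f_price: float, tot_pt: float) -> float:
    """Nationwide budget impact: full price per patient times the candidate
    population.  This is the undiscounted worst case, not the decay-adjusted
    expenditure."""
    if f_price <= 0:
        raise DomainError(f"f_price must be positive, got {f_price!r}")
    if tot_pt <= 0:
        raise DomainError(f"tot_pt must be positive, got {tot_pt!r}")
    return f_price * tot_pt


def _require_valid_model(model: PriceVolumeModel) -> None:
    if model.decay_k < 0:
        raise DomainError("expenditure is not defined for a rising-price model")


def total_expenditure_analytic(model: PriceVolumeModel, n: float) -> ExpenditureSummary:
    """Closed-form total expenditure over the first ``n`` treated patients."""
    _require_valid_model(model)
    if n <= 0:
        raise DomainError(f"n must be positive, got {n!r}")
    if model.decay_k == 0:
        total = model.f_price * n
    else:
        total = model.f_price * (1.0 - math.exp(-model.decay_k * n)) / model.decay_k
    return ExpenditureSummary(
        total=total,
        average_per_patient=total / n,
        n_patients=n,
        method=ExpenditureMethod.ANALYTIC,
    )


def total_expenditure_trapezoid(
    model: PriceVolumeModel, n: float, step: float
) -> ExpenditureSummary:
    """Composite trapezoidal AUC of the price curve over [0, n].

    Uniform panels of width ``step``; a final partial panel covers any
    remainder exactly.  Overestimates the analytic total (the integrand is
    convex) with error O(step^2).
    """
    _require_valid_model(model)
    if n <= 0:
        raise DomainError(f"n must be positive, got {n!r}")
    if not (0 < step <= n):
        raise DomainError(f"step must satisfy 0 < step <= n, got {step!r}")
    grid = np.arange(0.0, n, step)
    grid = np.append(grid, n)
    total = float(np.trapezoid(price_at(model, grid), grid))
    return ExpenditureSummary(
        total=total,
        average_per_patient=total / n,
        n_patients=n,
        method=ExpenditureMethod.TRAPEZOID,
        step=step,
    )


def average_cost_closed_form(model: PriceVolumeModel, tot_pt: float) -> float:
    """Average cost per patient over ``tot_pt`` treated patients.

    Uses (fPRICE - PRICE_last) / (k * totPT), with PRICE_last the modelled
    price at ``tot_pt`` — the same quantity as the analytic total divided by
    ``tot_pt``, in the form convenient when the endpoint prices are at hand.
    """
    _require_valid_model(model)
    if tot_pt <= 0:
        raise DomainError(f"tot_pt must be positive, got {tot_pt!r}")
    if model.decay_k == 0:
        return model.f_price
    price_last = price_at(model, tot_pt)
    return (model.f_price - price_last) / (model.decay_k * tot_pt)


def solve_decay_for_budget(
    f_price: float,
    tot_pt: float,
    budget_cap: float,
    half_life_const: float = HALF_LIFE_CONST,
) -> PriceVolumeModel:
    """Decay constant whose total expenditure over ``tot_pt`` hits a budget cap.

    Total expenditure is strictly decreasing in ``k`` at fixed ``f_price``
    and ``tot_pt``, so the root is unique; it is found by bracketed
    root-finding (Brent) to relative 1e-10 on the total.  A cap at or above
    the undiscounted spend ``f_price * tot_pt`` needs no decay and returns
    the flat model (``decay_k = 0``); check ``result.decay_k == 0`` for the
    no-discount case.
    """
    if budget_cap <= 0:
        raise DomainError(f"budget_cap must be positive, got {budget_cap!r}")
    undiscounted = nwbi(f_price, tot_pt)
    if budget_cap >= undiscounted:
        return PriceVolumeModel(f_price=f_price, decay_k=0.0, half_life_const=half_life_const)

    def excess(k: float) -> float:
        if k == 0.0:
            return undiscounted - budget_cap
        return f_price * (1.0 - math.exp(-k * tot_pt)) / k - budget_cap

    # Upper bracket: decay so fast the price hits 1 cent within one patient;
    # expand in the (pathological) case the cap is still below the total there.
    k_hi = math.log(f_price / 0.01)
    while excess(k_hi) > 0:
        k_hi *= 2.0
    k = brentq(excess, 0.0, k_hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    model = PriceVolumeModel(f_price=f_price, decay_k=float(k), half_life_const=half_life_const)
    total = total_expenditure_analytic(model, tot_pt).total
    assert abs(total - budget_cap) / budget_cap < 1e-10
    return model


def tier_schedule(
    model: PriceVolumeModel, band_edges: list[float]
) -> list[tuple[tuple[float, float], float]]:
    """Convert the continuous decay into a stepped (tiered) price schedule.

    Real agreements are usually written as flat prices over volume bands
    rather than a continuous curve.  Bands are [0, e1), [e1, e2), ... for the
    strictly ascending ``band_edges``; each band gets the volume-averaged
    model price over the band (band AUC / band width), so the schedule's
    total expenditure over any whole band equals the continuous model's.

    Returns a list of ``((lo, hi), flat_price_eur)`` pairs.
    """
    _require_valid_model(model)
    if not band_edges:
        raise DomainError("band_edges must be non-empty")
    edges = [0.0, *map(float, band_edges)]
    for lo, hi in zip(edges, edges[1:]):
        if hi <= lo:
            raise DomainError(f"band_edges must be strictly ascending and > 0, got {band_edges!r}")
    schedule = []
    for lo, hi in zip(edges, edges[1:]):
        auc_hi = total_expenditure_analytic(model, hi).total
        auc_lo = total_expenditure_analytic(model, lo).total if lo > 0 else 0.0
        schedule.append(((lo, hi), (auc_hi - auc_lo) / (hi - lo)))
    return schedule
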