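"""Exponential price-volume model and fitting.

A price-volume agreement lets the per-patient treatment price fall as the
cumulative number of treated patients grows.  The model here is first-order
exponential decay, borrowed from pharmacokinetics with cumulative patients in
place of time::

    PRICE(n) = fPRICE * exp(-k * n)

where ``fPRICE`` is the full (undiscounted) price at n = 0 patients and ``k``
is the decay constant in patients^-1.  The characteristic scale of the decay
is the *price-halving population* (PHP): the number of treated patients over
which the price halves, PHP = c / k with c = 0.693 by default (ln 2 to three
decimals, the convention used when the model was introduced; exact ln 2 is
available via ``half_life_const``).

Because the model is log-linear, two observed (patients, price) pairs pin it
down exactly, and noisier data fit by ordinary least squares on log-price.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HALF_LIFE_CONST",
    "INFINITE_PHP",
    "PriceVolumePoint",
    "PriceVolumeModel",
    "price_at",
    "fit_two_points",
    "fit_log_linear",
    "php_of",
    "k_from_php",
]

#: Default half-life constant: the 3-decimal rounding of ln 2 used in the
#: published worked examples.  Pass ``half_life_const=math.log(2)`` for the
#: exact value.
HALF_LIFE_CONST: float = 0.693

#: Sentinel PHP for a flat-price (no-discount) agreement: decay_k == 0 means
#: the price never halves.
INFINITE_PHP: float = math.inf


class DomainError(ValueError):
    """An argument lies outside the model's domain (e.g. negative price)."""


class DegenerateInputError(ValueError):
    """Inputs are insufficient to determine a fit (e.g. duplicate volumes)."""


class MonotonicityError(ValueError):
    """Prices rise with volume where the agreement requires them to fall."""


@dataclass(frozen=True)
class PriceVolumePoint:
    """One observation: cumulative treated patients and price per patient.

    ``n_treated`` is real-valued, not integer-only: volumes may be prorated
    (e.g. vials divided by vials-per-course).
    """

    n_treated: float
    price: float  # EUR per patient

    def __post_init__(self) -> None:
        if not math.isfinite(self.price) or self.price <= 0:
            raise DomainError(f"price must be strictly positive, got {self.price!r}")
        if not math.isfinite(self.n_treated) or self.n_treated < 0:
            raise DomainError(
                f"n_treated must be non-negative, got {self.n_treated!r}"
            )


@dataclass(frozen=True)
class PriceVolumeModel:
    """A fitted exponential price-volume model.

    Parameters
    ----------
    f_price:
        Full price at zero treated patients, EUR per patient. Strictly positive.
    decay_k:
        First-order decay constant, patients^-1.  Non-negative for a valid
        agreement; a negative value can only arise from a noisy least-squares
        fit and is always accompanied by ``rising_price=True``.
    half_life_const:
        Dimensionless constant converting ``decay_k`` to the price-halving
        population, PHP = half_life_const / decay_k.  Default 0.693.
    residual_se:
        Residual standard error of a log-linear least-squares fit (log-EUR
        units), or None for exact two-point fits.
    rising_price:
        True when a least-squares fit produced a positive slope (price rising
        with volume).  Never set by exact fits, which reject such inputs.
    """

    f_price: float
    decay_k: float
    half_life_const: float = HALF_LIFE_CONST
    residual_se: float | None = field(default=None, compare=False)
    rising_price: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not math.isfinite(self.f_price) or self.f_price <= 0:
            raise DomainError(f"f_price must be strictly positive, got {self.f_price!r}")
        if not math.isfinite(self.decay_k):
            raise DomainError(f"decay_k must be finite, got {self.decay_k!r}")
        if self.half_life_const <= 0:
            raise DomainError(
                f"half_life_const must be positive, got {self.half_life_const!r}"
            )
        if self.decay_k < 0 and not self.rising_price:
            raise DomainError(
                "decay_k < 0 requires the rising_price flag (noisy-fit escape hatch)"
            )

    @property
    def php(self) -> float:
        """Price-halving population (patients); inf for a flat model."""
        return php_of(self)

    def price_at(self, n: float) -> float:
        return price_at(self, n)


def price_at(model: PriceVolumeModel, n: float) -> float:
    """Price per patient after ``n`` cumulative treated patients.

    Strictly decreasing in ``n`` when ``decay_k > 0``; constant ``f_price``
    for a flat model.  ``n`` may be a numpy array.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise DomainError("n must be non-negative")
    out = model.f_price * np.exp(-model.decay_k * n)
    return float(out) if out.ndim == 0 else out


def fit_two_points(
    p1: PriceVolumePoint,
    p2: PriceVolumePoint,
    half_life_const: float = HALF_LIFE_CONST,
) -> PriceVolumeModel:
    """Exact two-point fit of the decay model.

    The decay constant is the log-price drop per patient::

        k = (ln p1.price - ln p2.price) / (p2.n_treated - p1.n_treated)

    When the first point sits at n = 0 (the usual anchoring, since the full
    price is public even when the agreement is confidential) its price is the
    full price directly; otherwise the full price is back-extrapolated.

    Raises
    ------
    DegenerateInputError
        If the two volumes coincide.
    MonotonicityError
        If the later price exceeds the earlier one (rising price).
    """
    if p2.n_treated == p1.n_treated:
        raise DegenerateInputError("the two points must have distinct n_treated")
    if p1.n_treated > p2.n_treated:
        p1, p2 = p2, p1
    if p2.price > p1.price:
        raise MonotonicityError(
            f"price rises with volume ({p1.price} -> {p2.price}); "
            "a price-volume agreement requires non-increasing prices"
        )
    decay_k = (math.log(p1.price) - math.log(p2.price)) / (p2.n_treated - p1.n_treated)
    if p1.n_treated == 0:
        f_price = p1.price
    else:
        f_price = p1.price * math.exp(decay_k * p1.n_treated)
    return PriceVolumeModel(f_price=f_price, decay_k=decay_k, half_life_const=half_life_const)


def fit_log_linear(
    points: list[PriceVolumePoint],
    anchor_f_price: float | None = None,
    half_life_const: float = HALF_LIFE_CONST,
) -> PriceVolumeModel:
    """Least-squares fit of the decay model on log-transformed prices.

    The exponential decay is linear in log-price, so ordinary least squares of
    ``ln(price)`` on ``n_treated`` estimates slope ``-k`` and intercept
    ``ln(fPRICE)``.  With ``anchor_f_price`` supplied the intercept is fixed
    at ``ln(anchor_f_price)`` and only the slope is fitted (one-parameter
    constrained fit through the known full price).

    With exactly two points the result coincides with :func:`fit_two_points`
    (two-point OLS interpolates exactly).

    A fitted negative ``decay_k`` (rising price, possible under noise) is
    *returned*, flagged via ``rising_price=True``, never silently clamped;
    the caller decides whether to reject it.

    The returned model carries ``residual_se``, the residual standard error
    of the log-price regression (``None`` when there are no residual degrees
    of freedom).
    """
    if len(points) < 2:
        raise DegenerateInputError("need at least 2 points")
    n = np.array([p.n_treated for p in points], dtype=float)
    logp = np.array([math.log(p.price) for p in points], dtype=float)
    if np.unique(n).size < 2:
        raise DegenerateInputError("need at least 2 distinct n_treated values")

    if anchor_f_price is not None:
        if anchor_f_price <= 0:
            raise DomainError("anchor_f_price must be strictly positive")
        # minimize sum((logp - (log A - k n))^2) over k
        intercept = math.log(anchor_f_price)
        y = intercept - logp
        denom = float(n @ n)
        if denom == 0.0:
            raise DegenerateInputError("all points at n=0; slope is undetermined")
        slope = -float(n @ y) / denom  # slope of logp vs n
        f_price = anchor_f_price  # intercept fixed: no exp(log(.)) round-trip
        dof = len(points) - 1
    else:
        slope, intercept = np.polyfit(n, logp, 1)
        f_price = math.exp(float(intercept))
        dof = len(points) - 2

    if np.ptp(logp) == 0.0:  # all prices identical: exactly flat, no decay
        slope = 0.0
        f_price = points[0].price

    resid = logp - (intercept + slope * n)
    residual_se = math.sqrt(float(resid @ resid) / dof) if dof > 0 else None

    decay_k = -float(slope)
    return PriceVolumeModel(
        f_price=f_price,
        decay_k=decay_k,
        half_life_const=half_life_const,
        residual_se=residual_se,
        rising_price=decay_k < 0,
    )


def php_of(model: PriceVolumeModel) -> float:
    """Price-halving population: ``half_life_const / decay_k``, in patients.

    Computed on the unrounded decay constant; rounding to whole patients is a
    presentation concern only.  A flat model (``decay_k == 0``) returns the
    infinite sentinel.
    """
    if model.decay_k < 0:
        raise DomainError("PHP is undefined for a rising-price model")
    if model.decay_k == 0:
        return INFINITE_PHP
    return model.half_life_const / model.decay_k


def k_from_php(php: float, half_life_const: float = HALF_LIFE_CONST) -> float:
    """Decay constant implied by a price-halving population (inverse of php_of).

    Round-trips with :func:`php_of` to machine precision; the infinite
    sentinel maps back to ``decay_k = 0``.
    """
    if math.isinf(php):
        return 0.0
    if php <= 0:
        raise DomainError(f"php must be positive, got {php!r}")
    return half_life_const / php
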