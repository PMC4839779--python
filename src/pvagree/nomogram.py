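"""Nomogram linking nationwide budget impact to the price-halving population.

Payers that negotiated past price-volume agreements implicitly chose a decay
speed according to how threatening the drug's budget impact was: the larger
the NWBI, the faster the imposed decay, i.e. the smaller the PHP relative to
the candidate population.  The nomogram captures this as reference points
(NWBI, PHP as % of totPT) from settled agreements and, for a new drug,
suggests a PHP by interpolation at its NWBI.

NWBI spans orders of magnitude (hundreds of millions to tens of billions of
euros), so interpolation is linear in log10(NWBI).  Queries outside the
reference range never extrapolate silently: the nearest endpoint's value is
returned together with an explicit flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model import DegenerateInputError, DomainError, k_from_php
from .expenditure import Agreement, nwbi as _nwbi

__all__ = [
    "NomogramPoint",
    "Nomogram",
    "PhpPrediction",
    "build_nomogram",
    "predict_php_pct",
    "predict_php",
]


@dataclass(frozen=True)
class NomogramPoint:
    """One reference agreement: its NWBI and its PHP as a share of totPT."""

    nwbi: float  # EUR
    php_pct: float  # PHP as percentage of totPT

    def __post_init__(self) -> None:
        if self.nwbi <= 0:
            raise DomainError(f"nwbi must be positive, got {self.nwbi!r}")
        if self.php_pct <= 0:
            raise DomainError(f"php_pct must be positive, got {self.php_pct!r}")


@dataclass(frozen=True)
class Nomogram:
    """Ordered reference points with log10-linear interpolation between them."""

    points: tuple[NomogramPoint, ...]
    interpolation: str = "log_linear"

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise DegenerateInputError("a nomogram needs at least 2 reference points")
        xs = [p.nwbi for p in self.points]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise DegenerateInputError("reference nwbi values must be strictly ascending")
        if self.interpolation != "log_linear":
            raise DomainError(f"unknown interpolation mode {self.interpolation!r}")


@dataclass(frozen=True)
class PhpPrediction:
    """A nomogram query result; ``extrapolated`` marks out-of-range queries."""

    nwbi: float
    php_pct: float
    php: float | None  # patients; None for pct-only queries
    decay_k: float | None  # patients^-1; None for pct-only queries
    extrapolated: bool


def build_nomogram(agreements: list[Agreement]) -> Nomogram:
    """Build a nomogram from settled agreements.

    Each agreement contributes (nwbi = f_price * tot_pt,
    php_pct = 100 * PHP / tot_pt); points are sorted by ascending NWBI.
    Flat-price agreements (infinite PHP) carry no decay information and are
    excluded with a warning; duplicate NWBI values are rejected.
    """
    pts = []
    for a in agreements:
        if math.isinf(a.php):
            warnings.warn(
                f"agreement {a.drug!r} has a flat price (infinite PHP); excluded from nomogram",
                stacklevel=2,
            )
            continue
        pts.append(NomogramPoint(nwbi=a.nwbi, php_pct=100.0 * a.php / a.tot_pt))
    pts.sort(key=lambda p: p.nwbi)
    if any(b.nwbi == a.nwbi for a, b in zip(pts, pts[1:])):
        raise DegenerateInputError("duplicate nwbi values among reference agreements")
    return Nomogram(points=tuple(pts))


def predict_php_pct(nomogram: Nomogram, nwbi: float) -> PhpPrediction:
    """PHP as a percentage of totPT suggested for a drug with the given NWBI.

    Linear interpolation of php_pct against log10(nwbi) between the bracketing
    reference points; at a reference NWBI the reference's php_pct is returned
    exactly.  Outside the reference range the nearest endpoint's value is
    returned with ``extrapolated=True``.
    """
    if nwbi <= 0:
        raise DomainError(f"nwbi must be positive, got {nwbi!r}")
    xs = np.log10([p.nwbi for p in nomogram.points])
    ys = np.array([p.php_pct for p in nomogram.points])
    x = math.log10(nwbi)
    extrapolated = bool(x < xs[0] or x > xs[-1])
    php_pct = float(np.interp(x, xs, ys))  # np.interp clamps to endpoints
    return PhpPrediction(
        nwbi=nwbi, php_pct=php_pct, php=None, decay_k=None, extrapolated=extrapolated
    )


def predict_php(
    nomogram: Nomogram, f_price: float, tot_pt: float, half_life_const: float | None = None
) -> PhpPrediction:
    """Suggested PHP (patients) and implied decay constant for a new drug.

    Computes the drug's NWBI, looks up the percentage on the nomogram and
    applies it to the candidate population: PHP = php_pct/100 * totPT.
    """
    budget = _nwbi(f_price, tot_pt)
    pct = predict_php_pct(nomogram, budget)
    php = pct.php_pct / 100.0 * tot_pt
    k = k_from_php(php) if half_life_const is None else k_from_php(php, half_life_const)
    return PhpPrediction(
        nwbi=budget, php_pct=pct.php_pct, php=php, decay_k=k, extrapolated=pct.extrapolated
    )
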