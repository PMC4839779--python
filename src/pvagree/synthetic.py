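"""Synthetic price-volume observations from a known decay model.

Lets fitting and recovery be tested end-to-end without external data: draw
noisy (n_treated, price) pairs from a model with known parameters, fit, and
compare the estimate with the truth.

Noise is multiplicative log-normal by default — the model is linear in
log-price, so log-normal price noise is exactly Gaussian noise on the scale
the least-squares fit works on, and keeps every price strictly positive.
Additive EUR noise is available as an option.  Volumes are noise-free: the
payer counts patients exactly; only prices are uncertain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import DomainError, PriceVolumePoint

__all__ = ["SyntheticSpec", "generate"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic dataset.

    Identical spec (including seed) always yields an identical dataset.

    Attributes
    ----------
    f_price, decay_k:
        True model parameters (EUR; patients^-1).
    n_points:
        Number of observations, >= 2.
    n_max:
        Largest volume; volumes cover [0, n_max].
    noise_sigma:
        Standard deviation of the noise: log-scale for ``lognormal`` noise,
        EUR for ``additive``.
    seed:
        RNG seed.
    spacing:
        ``"even"`` (default) or ``"uniform"`` random volumes on [0, n_max].
    noise:
        ``"lognormal"`` (default) or ``"additive"``.
    """

    f_price: float
    decay_k: float
    n_points: int = 50
    n_max: float = 50_000.0
    noise_sigma: float = 0.05
    seed: int = 0
    spacing: str = "even"
    noise: str = "lognormal"

    def __post_init__(self) -> None:
        if self.f_price <= 0:
            raise DomainError(f"f_price must be positive, got {self.f_price!r}")
        if self.decay_k < 0:
            raise DomainError(f"decay_k must be non-negative, got {self.decay_k!r}")
        if self.n_points < 2:
            raise DomainError(f"n_points must be >= 2, got {self.n_points!r}")
        if self.n_max <= 0:
            raise DomainError(f"n_max must be positive, got {self.n_max!r}")
        if self.noise_sigma < 0:
            raise DomainError(f"noise_sigma must be non-negative, got {self.noise_sigma!r}")
        if self.spacing not in ("even", "uniform"):
            raise DomainError(f"spacing must be 'even' or 'uniform', got {self.spacing!r}")
        if self.noise not in ("lognormal", "additive"):
            raise DomainError(f"noise must be 'lognormal' or 'additive', got {self.noise!r}")


def generate(spec: SyntheticSpec) -> list[PriceVolumePoint]:
    """Draw ``spec.n_points`` noisy observations from the specified model.

    price_i = f_price * exp(-decay_k * n_i) * exp(eps_i),
    eps_i ~ Normal(0, noise_sigma^2), for log-normal noise; additive noise
    adds Normal EUR perturbations instead (clipped away from zero so prices
    stay positive).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.spacing == "even":
        n = np.linspace(0.0, spec.n_max, spec.n_points)
    else:
        n = np.sort(rng.uniform(0.0, spec.n_max, spec.n_points))
    clean = spec.f_price * np.exp(-spec.decay_k * n)
    if spec.noise == "lognormal":
        price = clean * np.exp(rng.normal(0.0, spec.noise_sigma, spec.n_points))
    else:
        price = clean + rng.normal(0.0, spec.noise_sigma, spec.n_points)
        price = np.maximum(price, math.ulp(0.0) + 1e-9)
    return [PriceVolumePoint(float(ni), float(pi)) for ni, pi in zip(n, price)]
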