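"""Per-cell event hazards and the mitotic partitioning rule.

Division and death are modeled as Poisson processes whose rates are
log-linear in a transform of the cell's ecDNA copy number ``k``::

    rate(k) = clamp(exp(alpha + beta * T(k)), rate_min, rate_max)

with ``T(k) = ln(1 + k)`` (default; power-law-like dosage dependence that
stays finite over the observed 0..1000+ copy range) or ``T(k) = k / k_scale``.
``beta = 0`` for both event types recovers the neutral model in which
hazards are constant across cells.

At division all copies are duplicated and the ``2k`` copies are partitioned
between the two daughters by a binomial draw with daughter fraction ``p``:
``p = 0.5`` is unbiased segregation; the biased mode draws ``p`` from a
truncated Gaussian centered near 0.6, matching live-imaging estimates of
asymmetric partitioning. Which daughter is favored is decided by a fair
coin at every division (``orientation="random"``), so segregation alone
leaves the population mean copy number unchanged in expectation while
inflating its variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Literal, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "HazardModel",
    "SegregationModel",
    "hazard",
    "draw_daughter_fraction",
    "segregate",
]

_TRANSFORMS = ("log1p", "linear")


@dataclass(frozen=True)
class HazardModel:
    """Log-linear dosage-dependent division and death hazards.

    Parameters
    ----------
    alpha_div, alpha_death:
        Log-rate intercepts (log of events per hour).
    beta_div, beta_death:
        Dimensionless dosage slopes; zero gives dosage-independent rates.
    dosage_transform:
        ``"log1p"`` uses T(k) = ln(1 + k); ``"linear"`` uses T(k) = k / k_scale.
    k_scale:
        Copy-number normalizer for the linear transform.
    rate_min, rate_max:
        Hard clamps, in events/hour, applied after exponentiation.
    """

    alpha_div: float = math.log(0.02)
    beta_div: float = 0.0
    alpha_death: float = math.log(0.005)
    beta_death: float = 0.0
    dosage_transform: Literal["log1p", "linear"] = "log1p"
    k_scale: float = 300.0
    rate_min: float = 1e-4
    rate_max: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha_div", "beta_div", "alpha_death", "beta_death", "k_scale", "rate_min", "rate_max"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"HazardModel.{name} must be finite, got {v!r}")
        if self.dosage_transform not in _TRANSFORMS:
            raise ValueError(f"dosage_transform must be one of {_TRANSFORMS}")
        if self.rate_min <= 0:
            raise ValueError("rate_min must be > 0")
        if self.rate_max < self.rate_min:
            raise ValueError("rate_max must be >= rate_min")
        if self.k_scale <= 0:
            raise ValueError("k_scale must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HazardModel":
        return cls(**d)


@dataclass(frozen=True)
class SegregationModel:
    """Daughter-fraction model for binomial partitioning of duplicated copies.

    ``mode="fixed"`` uses ``r_mean`` on every division; ``mode="sampled"``
    draws a fresh fraction from Gaussian(r_mean, r_sd) truncated to
    [0.5, 1). With ``orientation="random"`` a fair coin decides which
    daughter receives the larger expected share at each division.
    """

    mode: Literal["fixed", "sampled"] = "fixed"
    r_mean: float = 0.5
    r_sd: float = 0.0
    orientation: Literal["random", "fixed"] = "random"

    def __post_init__(self) -> None:
        if not (0.5 <= self.r_mean < 1.0):
            raise ValueError(f"r_mean must lie in [0.5, 1), got {self.r_mean}")
        if self.r_sd < 0:
            raise ValueError("r_sd must be >= 0")
        if self.mode not in ("fixed", "sampled"):
            raise ValueError("mode must be 'fixed' or 'sampled'")
        if self.orientation not in ("random", "fixed"):
            raise ValueError("orientation must be 'random' or 'fixed'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SegregationModel":
        return cls(**d)


def _transform(k, model: HazardModel):
    if model.dosage_transform == "log1p":
        return np.log1p(k)
    return np.asarray(k, dtype=float) / model.k_scale


def hazard(k, model: HazardModel, event: Literal["division", "death"]):
    """Evaluate the division or death hazard at copy number ``k``.

    ``k`` may be a scalar or an array of non-negative integers; the return
    matches the input shape. Rates are clamped to
    ``[model.rate_min, model.rate_max]`` events/hour.
    """
    karr = np.asarray(k)
    if np.any(karr < 0):
        raise ValueError("copy number k must be non-negative")
    if event == "division":
        alpha, beta = model.alpha_div, model.beta_div
    elif event == "death":
        alpha, beta = model.alpha_death, model.beta_death
    else:
        raise ValueError("event must be 'division' or 'death'")
    rate = np.exp(alpha + beta * _transform(karr, model))
    rate = np.clip(rate, model.rate_min, model.rate_max)
    if np.isscalar(k) or karr.ndim == 0:
        return float(rate)
    return rate


def draw_daughter_fraction(seg: SegregationModel, rng: np.random.Generator) -> float:
    """Draw one daughter fraction p in [0.5, 1).

    Fixed mode returns ``r_mean`` exactly. Sampled mode draws from
    Gaussian(r_mean, r_sd) truncated to [0.5, 1); ``r_sd = 0`` degenerates
    to ``r_mean``.
    """
    if seg.mode == "fixed" or seg.r_sd == 0.0:
        return seg.r_mean
    a = (0.5 - seg.r_mean) / seg.r_sd
    b = (1.0 - seg.r_mean) / seg.r_sd
    # scipy truncnorm handles the boundary weights exactly
    return float(stats.truncnorm.rvs(a, b, loc=seg.r_mean, scale=seg.r_sd, random_state=rng))


def segregate(k: int, seg: SegregationModel, rng: np.random.Generator) -> Tuple[int, int]:
    """Duplicate ``k`` copies and partition the 2k copies between daughters.

    Returns ``(k1, k2)`` with ``k1 + k2 = 2k`` always. ``k1`` is binomial
    with success probability ``p`` (or ``1 - p`` on the flip of a fair coin
    when ``orientation="random"``).
    """
    k = int(k)
    if k < 0:
        raise ValueError("copy number k must be non-negative")
    if k == 0:
        return 0, 0
    p = draw_daughter_fraction(seg, rng)
    if seg.orientation == "random" and rng.random() < 0.5:
        p = 1.0 - p
    k1 = int(rng.binomial(2 * k, p))
    return k1, 2 * k - k1
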