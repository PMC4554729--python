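"""Distance-dependent encounter-rate models.

The encounter process is a per-occasion Bernoulli with a complementary
log-log link: an individual with activity center at distance d from a trap
has encounter rate lambda(d) and per-occasion capture probability
p = 1 - exp(-lambda(d)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConsistencyError, DomainError

__all__ = ["DetectionParams", "detection_rate", "encounter_prob", "KINDS"]

KINDS = ("half_normal", "neg_exponential", "non_spatial")


@dataclass(frozen=True)
class DetectionParams:
    """Baseline rate lam0 (per occasion), spatial scale sigma (m), and kind."""

    lam0: float
    sigma: float | None = None
    kind: str = "half_normal"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConsistencyError(f"unknown detection kind {self.kind!r}")
        if self.lam0 < 0:
            raise DomainError("lam0 must be nonnegative")
        if self.kind != "non_spatial" and (self.sigma is None or self.sigma <= 0):
            raise DomainError("sigma must be positive for spatial detection kinds")


def detection_rate(d, params: DetectionParams):
    """Expected encounter rate at trap-center distance d (m).

    half_normal:     lam0 * exp(-d^2 / (2 sigma^2))
    neg_exponential: lam0 * exp(-d / sigma)
    non_spatial:     lam0 for every d
    """
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise DomainError("distance must be nonnegative")
    if params.kind == "half_normal":
        out = params.lam0 * np.exp(-(d**2) / (2.0 * params.sigma**2))
    elif params.kind == "neg_exponential":
        out = params.lam0 * np.exp(-d / params.sigma)
    else:
        out = np.full_like(d, params.lam0)
    return out if out.ndim else float(out)


def encounter_prob(rate):
    """Per-occasion capture probability p = 1 - exp(-rate)."""
    rate = np.asarray(rate, dtype=float)
    if (rate < 0).any():
        raise DomainError("rate must be nonnegative")
    out = -np.expm1(-rate)
    return out if out.ndim else float(out)


def rate_from_sq_distance(d2, lam0: float, sigma: float, kind: str):
    """detection_rate evaluated on squared distances (sampler hot path)."""
    if kind == "half_normal":
        return lam0 * np.exp(-d2 / (2.0 * sigma * sigma))
    if kind == "neg_exponential":
        return lam0 * np.exp(-np.sqrt(d2) / sigma)
    return np.full_like(np.asarray(d2, dtype=float), lam0)
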