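"""Convergence and goodness-of-fit diagnostics for SECR chains."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from ..errors import ConsistencyError, DomainError
from .detection import rate_from_sq_distance
from .sampler import SECRPosterior

__all__ = ["geweke", "bayesian_p_value", "spectral_density_at_zero"]


def spectral_density_at_zero(x: np.ndarray) -> float:
    """Bartlett-windowed estimate of the spectral density at frequency zero.

    Equals the long-run variance of the chain; reduces to the sample
    variance for white noise.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    xc = x - x.mean()
    gamma0 = float(xc @ xc) / n
    bandwidth = int(4 * (n / 100.0) ** (2.0 / 9.0))
    s = gamma0
    for lag in range(1, min(bandwidth, n - 1) + 1):
        gamma = float(xc[lag:] @ xc[:-lag]) / n
        s += 2.0 * (1.0 - lag / (bandwidth + 1.0)) * gamma
    return max(s, 0.0)


def geweke(chain, first: float = 0.1, last: float = 0.5) -> float:
    """Convergence z-score comparing early and late chain segments.

    Difference of window means standardized by spectral-density-at-zero
    variance estimates. Returns NaN when either window has zero variance
    (the statistic is undefined for constant segments — callers should
    treat NaN as a flagged result, except for the exactly-identical-window
    case, which scores 0 by convention).
    """
    x = np.asarray(chain, dtype=float)
    n = x.shape[0]
    if n < 100:
        raise DomainError("geweke needs a chain of length >= 100")
    a = x[: int(first * n)]
    b = x[n - int(last * n):]
    diff = float(a.mean() - b.mean())
    va = spectral_density_at_zero(a) / a.shape[0]
    vb = spectral_density_at_zero(b) / b.shape[0]
    denom = va + vb
    if denom == 0.0:
        return 0.0 if diff == 0.0 else float("nan")
    return diff / float(np.sqrt(denom))


def bayesian_p_value(
    posterior: SECRPosterior,
    history=None,
    max_draws: int = 2000,
    seed: int = 0,
) -> float:
    """Posterior-predictive fit probability via the Freeman-Tukey statistic.

    For each retained draw, individual encounter totals y_i. are compared
    with their conditional expectations E[y_i.] = sum_j K_j p_ij at the
    drawn activity centers: T = sum_i (sqrt(y_i.) - sqrt(E[y_i.]))^2.
    Replicated totals are simulated from the same draw; the p-value is
    Pr(T_rep >= T_obs) over draws (ties count as >=).
    """
    history = history if history is not None else posterior.history
    if history is None or posterior.s_obs is None or posterior.state_space is None:
        raise ConsistencyError("posterior lacks the latent states needed for the check")
    rng = np.random.default_rng(seed)
    traps = posterior.traps
    d2 = cdist(posterior.state_space.coords(), traps.coords(), "sqeuclidean")
    k_j = traps.activity.sum(axis=1)
    y_tot = history.y.sum(axis=(1, 2)).astype(float)
    kind = posterior.settings.get("kind", "half_normal")

    n_draws = posterior.n_saved
    take = np.linspace(0, n_draws - 1, min(max_draws, n_draws)).astype(int)
    hits = 0
    for t in take:
        lam = rate_from_sq_distance(
            d2[posterior.s_obs[t]], posterior.lam0[t], posterior.sigma[t], kind
        )
        p = -np.expm1(-lam)
        expected = (p * k_j).sum(axis=1)
        t_obs = float(((np.sqrt(y_tot) - np.sqrt(expected)) ** 2).sum())
        y_rep = rng.binomial(k_j.astype(int)[None, :], p).sum(axis=1)
        t_rep = float(((np.sqrt(y_rep) - np.sqrt(expected)) ** 2).sum())
        hits += t_rep >= t_obs
    return hits / take.shape[0]
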