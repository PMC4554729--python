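"""Data-augmented non-spatial (constant-p) abundance model.

Same augmentation machinery as the spatial sampler, but capture is a
per-occasion Bernoulli with a single probability p regardless of trap or
distance: an individual's daily detection y_ik = max_j y_ijk, so
y_i. ~ Binomial(K, p) for included individuals. All full conditionals are
conjugate, so the sampler is pure Gibbs.

Density needs an externally supplied effective area; without one the
output is abundance-only.
"""

from __future__ import annotations

import numpy as np

from ..data_model import CaptureHistory
from ..errors import ConfigError
from .sampler import SECRPosterior

__all__ = ["fit_nonspatial", "NonSpatialConfig"]


def fit_nonspatial(
    history: CaptureHistory,
    n_augment: int = 200,
    iterations: int = 60_000,
    burn_in: int = 10_000,
    thin: int = 1,
    seed: int = 0,
    effective_area_km2: float | None = None,
) -> SECRPosterior:
    """Gibbs sampler for the augmented constant-p model.

    Returns a SECRPosterior with ``sigma`` absent (None) and the
    per-occasion capture probability reported in the ``lam0`` slot.
    """
    if iterations <= burn_in:
        raise ConfigError("iterations must exceed burn_in")
    rng = np.random.default_rng(seed)
    n_obs = history.n_individuals
    M = n_obs + n_augment
    K = history.n_occasions
    y_days = history.y.any(axis=1).sum(axis=1).astype(int)  # daily detections

    z = np.zeros(M, dtype=bool)
    z[:n_obs] = True
    psi, p = 0.5, max(float(y_days.mean()) / K, 1.0 / K)

    n_saved = (iterations - burn_in) // thin
    p_c = np.empty(n_saved)
    psi_c = np.empty(n_saved)
    n_c = np.empty(n_saved, dtype=np.int64)

    y_aug = np.zeros(M, dtype=int)
    y_aug[:n_obs] = y_days
    t = 0
    for it in range(iterations):
        # z for augmented all-zero rows
        a = psi * (1.0 - p) ** K
        pz = a / (a + (1.0 - psi))
        z[n_obs:] = rng.random(M - n_obs) < pz
        nz = int(z.sum())
        psi = float(rng.beta(1 + nz, 1 + M - nz))
        succ = int(y_aug[z].sum())
        p = float(rng.beta(1 + succ, 1 + nz * K - succ))
        if it >= burn_in and (it - burn_in) % thin == 0:
            p_c[t] = p
            psi_c[t] = psi
            n_c[t] = nz
            t += 1

    density = n_c / effective_area_km2 * 100.0 if effective_area_km2 else None
    return SECRPosterior(
        lam0=p_c,
        sigma=None,
        psi=psi_c,
        N=n_c,
        density=density,
        pixel_mean=None,
        s_obs=None,
        suitable_area_km2=effective_area_km2 if effective_area_km2 else float("nan"),
        M=M,
        n_observed=n_obs,
        settings={
            "iterations": iterations,
            "burn_in": burn_in,
            "thin": thin,
            "kind": "non_spatial",
            "seed": seed,
            "n_augment": n_augment,
        },
        history=history,
    )
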