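"""Empirical variogram fitting and ordinary kriging.

Small, dense implementation: survey datasets here are tens of points, so
the kriging system is factorized once and solved for all prediction
targets simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from ..errors import ConsistencyError, DomainError

__all__ = ["VariogramModel", "fit_variogram", "ordinary_kriging", "KrigingResult"]

_MODEL_KINDS = ("exponential", "spherical")


@dataclass(frozen=True)
class VariogramModel:
    """Semivariogram gamma(d) = nugget + psill * f(d / range)."""

    nugget: float
    psill: float  # partial sill; total sill = nugget + psill
    range_m: float
    kind: str = "exponential"
    pure_nugget: bool = False

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    def gamma(self, d):
        d = np.asarray(d, dtype=float)
        if self.kind == "exponential":
            struct = 1.0 - np.exp(-d / self.range_m)
        elif self.kind == "spherical":
            h = np.minimum(d / self.range_m, 1.0)
            struct = 1.5 * h - 0.5 * h**3
        else:
            raise ConsistencyError(f"unknown variogram kind {self.kind!r}")
        g = self.nugget + self.psill * struct
        return np.where(d > 0, g, 0.0)


def empirical_variogram(
    points, values, n_bins: int = 12, max_dist: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned semivariances: returns (bin center, gamma, n_pairs)."""
    pts = np.asarray(points, dtype=float)
    v = np.asarray(values, dtype=float)
    d = cdist(pts, pts)
    iu = np.triu_indices(len(v), k=1)
    dist = d[iu]
    semiv = 0.5 * (v[iu[0]] - v[iu[1]]) ** 2
    if max_dist is None:
        max_dist = dist.max() / 2.0
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    centers, gammas, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dist > lo) & (dist <= hi)
        if sel.sum() == 0:
            continue
        centers.append(dist[sel].mean())
        gammas.append(semiv[sel].mean())
        counts.append(int(sel.sum()))
    return np.array(centers), np.array(gammas), np.array(counts)


def fit_variogram(
    points, values, model_kind: str = "exponential", n_bins: int = 12,
    max_dist: float | None = None,
) -> VariogramModel:
    """Fit a variogram model to the binned empirical semivariogram by WLS.

    Weights are the pair counts per bin. Requires >= 5 points; a constant
    field returns a pure-nugget model with (near-)zero sill.
    """
    if model_kind not in _MODEL_KINDS:
        raise ConsistencyError(f"model_kind must be one of {_MODEL_KINDS}")
    pts = np.asarray(points, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(v) < 5:
        raise DomainError("variogram fitting needs at least 5 points")
    if np.allclose(v, v[0]):
        d = cdist(pts, pts)
        return VariogramModel(0.0, 0.0, max(d.max(), 1.0), model_kind, pure_nugget=True)

    centers, gammas, counts = empirical_variogram(pts, v, n_bins, max_dist)
    var = float(v.var())
    x0 = np.array([min(gammas.min(), var * 0.1), max(var - gammas.min(), var * 0.1), centers.max() / 3.0])

    def resid(theta):
        model = VariogramModel(theta[0], theta[1], theta[2], model_kind)
        return np.sqrt(counts) * (model.gamma(centers) - gammas)

    fit = least_squares(
        resid, x0,
        bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, 100.0 * centers.max()]),
    )
    nugget, psill, rng = (float(t) for t in fit.x)
    pure = psill <= 1e-12 * max(var, 1.0)
    return VariogramModel(nugget, psill, rng, model_kind, pure_nugget=pure)


@dataclass(frozen=True)
class KrigingResult:
    predictions: np.ndarray
    variances: np.ndarray
    weights: np.ndarray  # (n_targets, n_points), rows sum to 1
    n_duplicates_merged: int = 0


def ordinary_kriging(
    points, values, targets, variogram: VariogramModel, log_transform: bool = False,
) -> KrigingResult:
    """Solve the ordinary-kriging system for every target location.

    Duplicate data locations are merged (values averaged) before building
    the system, since they make it singular; the count of merged rows is
    reported. With ``log_transform`` the model is fitted to log(value + c),
    c = half the smallest positive observation, and predictions are
    back-transformed with the lognormal bias correction
    exp(pred + var/2) - c.

    Note: when log-transforming, the supplied variogram must describe the
    log-scale values.
    """
    pts = np.asarray(points, dtype=float)
    v = np.asarray(values, dtype=float)
    tg = np.asarray(targets, dtype=float)
    if tg.ndim != 2 or tg.shape[0] == 0:
        raise DomainError("targets must be a nonempty (m, 2) array")

    # merge exact-duplicate locations
    uniq, inverse = np.unique(pts, axis=0, return_inverse=True)
    n_dup = len(pts) - len(uniq)
    if n_dup:
        sums = np.zeros(len(uniq))
        counts = np.zeros(len(uniq))
        np.add.at(sums, inverse, v)
        np.add.at(counts, inverse, 1.0)
        pts, v = uniq, sums / counts

    c = 0.0
    if log_transform:
        pos = v[v > 0]
        c = float(pos.min()) / 2.0 if pos.size else 1.0
        v = np.log(v + c)

    n = len(v)
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = variogram.gamma(cdist(pts, pts))
    a[n, :] = 1.0
    a[:, n] = 1.0
    a[n, n] = 0.0
    b = np.empty((n + 1, tg.shape[0]))
    b[:n, :] = variogram.gamma(cdist(pts, tg))
    b[n, :] = 1.0
    try:
        sol = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise ConsistencyError(f"singular kriging system: {exc}") from exc

    w = sol[:n, :]
    mu = sol[n, :]
    pred = w.T @ v
    var = np.maximum((w * b[:n, :]).sum(axis=0) + mu, 0.0)
    if log_transform:
        pred = np.exp(pred + var / 2.0) - c
    return KrigingResult(
        predictions=pred, variances=var, weights=w.T, n_duplicates_merged=n_dup
    )
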