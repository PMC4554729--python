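"""Metropolis-within-Gibbs sampler for data-augmented SECR.

Model: the observed n individuals are augmented with all-zero capture
histories up to M = n + n_augment. Each row i has a latent inclusion flag
z_i ~ Bernoulli(psi) and a latent activity-center pixel s_i uniform over
suitable state-space pixels. Given inclusion, captures are independent
per-occasion Bernoulli events with probability 1 - exp(-lambda(d_ij)),
where lambda is the distance-dependent encounter rate.

Updates per iteration:
  * s_i: for included individuals, a symmetric uniform jump on the pixel
    grid within a configurable radius (Metropolis); for excluded ones the
    full conditional is uniform over suitable pixels and is drawn directly.
  * z_i (augmented rows): Gibbs from its Bernoulli full conditional.
  * psi: Gibbs from Beta(1 + sum z, 1 + M - sum z).
  * lam0, sigma: log-scale random-walk Metropolis with uniform priors on
    the natural scale (Jacobian included); proposal scales are adapted
    during burn-in only and frozen afterwards.

Because the per-occasion probability is constant over occasions, the
likelihood depends on the data only through per-trap capture counts
n_ij = sum_k y_ijk and per-trap effort K_j = sum_k activity_jk.

An optional global behavioral response (off by default) multiplies the
encounter rate by exp(beta) on every occasion after an individual's first
capture anywhere; with it enabled the sufficient statistics split into
pre/post first-capture effort and counts, and beta gets a plain
random-walk Metropolis update. When disabled, beta is fixed at 0 and its
saved chain is constant zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.spatial.distance import cdist

from ..data_model import CaptureHistory, TrapArray
from ..errors import ConfigError, ConsistencyError, DomainError
from ..state_space import StateSpace, build_state_space
from .detection import KINDS, rate_from_sq_distance

__all__ = [
    "FitConfig",
    "SECRPosterior",
    "fit_secr",
    "pixel_density_map",
    "buffer_sensitivity",
    "prior_sensitivity",
]

_TARGET_ACCEPT = 0.44
_ADAPT_BLOCK = 50


@dataclass(frozen=True)
class FitConfig:
    """MCMC settings. Defaults follow the reference analysis protocol."""

    seed: int
    n_augment: int = 200
    iterations: int = 60_000
    burn_in: int = 10_000
    thin: int = 1
    kind: str = "half_normal"
    lam0_max: float = 5.0
    sigma_max: float | None = None  # default: 5 x trap-array diagonal
    lam0_init: float | None = None
    sigma_init: float | None = None
    proposal_lam0: float = 0.3  # log-scale RW sd
    proposal_sigma: float = 0.3
    proposal_radius: int = 5  # pixels
    adapt: bool = True
    behavioral_response: bool = False  # global trap response, beta fixed 0 when off
    beta_max: float = 5.0  # uniform prior half-width for beta
    proposal_beta: float = 0.3

    def __post_init__(self) -> None:
        if self.kind not in KINDS or self.kind == "non_spatial":
            raise ConfigError(f"fit_secr supports spatial kinds, not {self.kind!r}")
        if self.iterations <= self.burn_in:
            raise ConfigError("iterations must exceed burn_in")
        if self.thin < 1 or self.n_augment < 1:
            raise ConfigError("thin and n_augment must be >= 1")


@dataclass
class SECRPosterior:
    """Post-burn-in chains plus latent-state bookkeeping.

    Per-pixel inclusion counts are stored as their running mean over saved
    iterations (``pixel_mean``); activity-center chains are kept for the
    observed individuals only (``s_obs``), which is what the
    posterior-predictive check needs.
    """

    lam0: np.ndarray
    sigma: np.ndarray | None
    psi: np.ndarray
    N: np.ndarray
    density: np.ndarray
    pixel_mean: np.ndarray | None
    s_obs: np.ndarray | None  # (n_saved, n_observed) pixel indices
    suitable_area_km2: float
    M: int
    n_observed: int
    beta: np.ndarray | None = None  # behavioral response; constant 0 when disabled
    settings: dict[str, Any] = field(default_factory=dict)
    accept_rates: dict[str, float] = field(default_factory=dict)
    state_space: StateSpace | None = None
    traps: TrapArray | None = None
    history: CaptureHistory | None = None

    @property
    def n_saved(self) -> int:
        return self.psi.shape[0]

    def chains(self) -> dict[str, np.ndarray]:
        out = {"lam0": self.lam0, "psi": self.psi, "N": self.N}
        if self.density is not None:
            out["density"] = self.density
        if self.sigma is not None:
            out["sigma"] = self.sigma
        if self.beta is not None:
            out["beta"] = self.beta
        return out


def fit_secr(
    history: CaptureHistory,
    traps: TrapArray,
    state_space: StateSpace,
    config: FitConfig,
) -> SECRPosterior:
    """Run the data-augmented SECR sampler and return saved chains."""
    history.validate_against(traps)
    sampler = _Sampler(history, traps, state_space, config)
    return sampler.run()


class _Sampler:
    def __init__(
        self,
        history: CaptureHistory,
        traps: TrapArray,
        state_space: StateSpace,
        config: FitConfig,
    ) -> None:
        self.config = config
        self.ss = state_space
        self.traps = traps
        self.history = history
        self.rng = np.random.default_rng(config.seed)

        self.n_obs = history.n_individuals
        self.M = self.n_obs + config.n_augment
        if self.M <= self.n_obs:
            raise ConfigError("augmented size M must exceed the number observed")

        self.nmat = history.y.sum(axis=2).astype(float)  # (n_obs, J)
        self.K = traps.activity.sum(axis=1).astype(float)  # effort per trap

        # pre/post first-capture splits for the optional behavioral response;
        # augmented rows are never captured, so their effort is all "pre"
        J = traps.n_traps
        self.nall = np.zeros((self.M, J))
        self.nall[: self.n_obs] = self.nmat
        self.npre = np.zeros((self.M, J))
        self.npost = np.zeros((self.M, J))
        self.kpre = np.tile(self.K, (self.M, 1))
        self.kpost = np.zeros((self.M, J))
        activity = traps.activity.astype(float)
        for i in range(self.n_obs):
            first = int(np.flatnonzero(history.y[i].any(axis=0))[0])
            pre = np.zeros(history.n_occasions)
            pre[: first + 1] = 1.0  # response starts after the first capture
            self.kpre[i] = activity @ pre
            self.kpost[i] = self.K - self.kpre[i]
            self.npre[i] = history.y[i].astype(float) @ pre
            self.npost[i] = self.nmat[i] - self.npre[i]
        coords = state_space.coords()
        self.d2 = cdist(coords, traps.coords(), "sqeuclidean")  # (npix, J)
        self.suit_idx = np.flatnonzero(state_space.suitable)
        self.lookup = state_space.grid_lookup()
        self.area = state_space.suitable_area_km2

        diag = float(np.hypot(np.ptp(traps.x), np.ptp(traps.y)))
        diag = max(diag, state_space.spacing_m)  # single-trap degenerate case
        self.sigma_max = config.sigma_max if config.sigma_max is not None else 5.0 * diag
        self.lam0 = config.lam0_init if config.lam0_init is not None else 0.01
        self.sigma = config.sigma_init if config.sigma_init is not None else max(diag / 8.0, state_space.spacing_m)
        if not (0 < self.lam0 <= config.lam0_max and 0 < self.sigma <= self.sigma_max):
            raise ConfigError("initial lam0/sigma outside their prior support")

        self.beta = 0.0
        self.psi = 0.5
        self.z = np.zeros(self.M, dtype=bool)
        self.z[: self.n_obs] = True
        self.z[self.n_obs :] = self.rng.random(self.M - self.n_obs) < self.psi
        self.s = np.empty(self.M, dtype=np.int64)
        self._init_centers()

        self.tau = {
            "lam0": config.proposal_lam0,
            "sigma": config.proposal_sigma,
            "beta": config.proposal_beta,
        }
        self.accepts = {"lam0": 0, "sigma": 0, "beta": 0, "s": 0}
        self.proposals = {"lam0": 0, "sigma": 0, "beta": 0, "s": 0}
        self._block_acc = {"lam0": 0, "sigma": 0, "beta": 0}

        if not np.isfinite(self._ll_obs(self.lam0, self.sigma)):
            raise ConsistencyError(
                "non-finite likelihood at initialization (check lam0/sigma inits)"
            )

    # -- likelihood pieces ---------------------------------------------------

    def _rates(self, pix: np.ndarray, lam0: float, sigma: float) -> np.ndarray:
        return rate_from_sq_distance(self.d2[pix], lam0, sigma, self.config.kind)

    def _ll_rows(
        self, pix: np.ndarray, idx: np.ndarray, lam0: float, sigma: float, beta: float
    ) -> np.ndarray:
        """Log-likelihood of rows ``idx`` with activity centers at ``pix``.

        With beta = 0 a single binomial block suffices (identity:
        sum_j [n log p - (K-n) L] = -(L @ K) + sum_{n>0} n (L + log p));
        otherwise pre/post first-capture blocks are evaluated at rates L
        and L*exp(beta) respectively.
        """
        lam = self._rates(pix, lam0, sigma)
        if beta == 0.0:
            nrows = self.nall[idx]
            ll = -(lam @ self.K)
            if nrows.any():
                with np.errstate(divide="ignore", invalid="ignore"):
                    logp = np.log(-np.expm1(-lam))
                    ll = ll + np.where(nrows > 0, nrows * (lam + logp), 0.0).sum(axis=1)
            return ll
        ll = np.zeros(pix.shape[0])
        for n, k, rate in (
            (self.npre[idx], self.kpre[idx], lam),
            (self.npost[idx], self.kpost[idx], lam * np.exp(beta)),
        ):
            ll -= ((k - n) * rate).sum(axis=1)
            if n.any():
                with np.errstate(divide="ignore", invalid="ignore"):
                    logp = np.log(-np.expm1(-rate))
                    ll += np.where(n > 0, n * logp, 0.0).sum(axis=1)
        return ll

    def _ll_obs(self, lam0: float, sigma: float, beta: float | None = None) -> float:
        """Joint log-likelihood of all currently included individuals."""
        beta = self.beta if beta is None else beta
        idx = np.flatnonzero(self.z)
        return float(self._ll_rows(self.s[idx], idx, lam0, sigma, beta).sum())

    # -- initialization ------------------------------------------------------

    def _init_centers(self) -> None:
        suit_coords = self.ss.coords()[self.suit_idx]
        for i in range(self.n_obs):
            w = self.nmat[i]
            cx = float(np.average(self.traps.x, weights=w))
            cy = float(np.average(self.traps.y, weights=w))
            j = int(np.argmin((suit_coords[:, 0] - cx) ** 2 + (suit_coords[:, 1] - cy) ** 2))
            self.s[i] = self.suit_idx[j]
        self.s[self.n_obs :] = self.rng.choice(self.suit_idx, size=self.M - self.n_obs)

    # -- update steps --------------------------------------------------------

    def _update_centers(self) -> None:
        rng = self.rng
        # excluded individuals: full conditional is uniform over suitable pixels
        off = np.flatnonzero(~self.z)
        if off.size:
            self.s[off] = rng.choice(self.suit_idx, size=off.size)

        idx = np.flatnonzero(self.z)
        m = idx.shape[0]
        r = self.config.proposal_radius
        dx = rng.integers(-r, r + 1, size=m)
        dy = rng.integers(-r, r + 1, size=m)
        gx = self.ss.ix[self.s[idx]] + dx
        gy = self.ss.iy[self.s[idx]] + dy
        ok = (gx >= 0) & (gx < self.ss.nx) & (gy >= 0) & (gy < self.ss.ny)
        prop = np.full(m, -1, dtype=np.int64)
        prop[ok] = self.lookup[gx[ok], gy[ok]]
        ok &= prop >= 0  # off-grid or unsuitable proposals are rejected

        sub = np.flatnonzero(ok)
        if sub.size:
            rows = idx[sub]
            cur_ll = self._ll_rows(self.s[rows], rows, self.lam0, self.sigma, self.beta)
            new_ll = self._ll_rows(prop[sub], rows, self.lam0, self.sigma, self.beta)
            accept = np.log(rng.random(sub.size)) < new_ll - cur_ll
            self.s[idx[sub[accept]]] = prop[sub[accept]]
            self.accepts["s"] += int(accept.sum())
        self.proposals["s"] += m

    def _update_inclusion(self) -> None:
        aug = np.arange(self.n_obs, self.M)
        lam = self._rates(self.s[aug], self.lam0, self.sigma)
        log_l0 = -(lam @ self.K)  # probability of an all-zero history
        a = self.psi * np.exp(log_l0)
        pz = a / (a + (1.0 - self.psi))
        self.z[aug] = self.rng.random(aug.shape[0]) < pz

    def _update_psi(self) -> None:
        nz = int(self.z.sum())
        self.psi = float(self.rng.beta(1 + nz, 1 + self.M - nz))

    def _update_detection(self) -> None:
        cur_ll = self._ll_obs(self.lam0, self.sigma)

        for name in ("lam0", "sigma"):
            cur = self.lam0 if name == "lam0" else self.sigma
            upper = self.config.lam0_max if name == "lam0" else self.sigma_max
            prop = cur * float(np.exp(self.rng.normal(0.0, self.tau[name])))
            self.proposals[name] += 1
            if prop <= upper:
                if name == "lam0":
                    prop_ll = self._ll_obs(prop, self.sigma)
                else:
                    prop_ll = self._ll_obs(self.lam0, prop)
                # log-scale RW on a natural-scale uniform prior: Jacobian prop/cur
                log_alpha = prop_ll - cur_ll + np.log(prop / cur)
                if np.log(self.rng.random()) < log_alpha:
                    if name == "lam0":
                        self.lam0 = prop
                    else:
                        self.sigma = prop
                    cur_ll = prop_ll
                    self.accepts[name] += 1
                    self._block_acc[name] += 1

        if self.config.behavioral_response:
            prop = self.beta + float(self.rng.normal(0.0, self.tau["beta"]))
            self.proposals["beta"] += 1
            if abs(prop) <= self.config.beta_max:
                prop_ll = self._ll_obs(self.lam0, self.sigma, beta=prop)
                if np.log(self.rng.random()) < prop_ll - cur_ll:
                    self.beta = prop
                    self.accepts["beta"] += 1
                    self._block_acc["beta"] += 1

    def _adapt(self) -> None:
        names = ("lam0", "sigma", "beta") if self.config.behavioral_response else ("lam0", "sigma")
        for name in names:
            rate = self._block_acc[name] / _ADAPT_BLOCK
            factor = float(np.exp(0.5 * (rate - _TARGET_ACCEPT)))
            self.tau[name] = float(np.clip(self.tau[name] * factor, 1e-3, 5.0))
            self._block_acc[name] = 0

    # -- main loop -----------------------------------------------------------

    def run(self) -> SECRPosterior:
        cfg = self.config
        n_saved = (cfg.iterations - cfg.burn_in) // cfg.thin
        lam0_c = np.empty(n_saved)
        sigma_c = np.empty(n_saved)
        beta_c = np.empty(n_saved)
        psi_c = np.empty(n_saved)
        n_c = np.empty(n_saved, dtype=np.int64)
        s_obs = np.empty((n_saved, self.n_obs), dtype=np.int64)
        pixel_sum = np.zeros(self.ss.n_pixels)

        t = 0
        for it in range(cfg.iterations):
            self._update_centers()
            self._update_inclusion()
            self._update_psi()
            self._update_detection()
            if cfg.adapt and it < cfg.burn_in and (it + 1) % _ADAPT_BLOCK == 0:
                self._adapt()
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                lam0_c[t] = self.lam0
                sigma_c[t] = self.sigma
                beta_c[t] = self.beta
                psi_c[t] = self.psi
                n_c[t] = int(self.z.sum())
                s_obs[t] = self.s[: self.n_obs]
                pixel_sum += np.bincount(self.s[self.z], minlength=self.ss.n_pixels)
                t += 1

        density = n_c / self.area * 100.0
        return SECRPosterior(
            lam0=lam0_c,
            sigma=sigma_c,
            beta=beta_c,
            psi=psi_c,
            N=n_c,
            density=density,
            pixel_mean=pixel_sum / max(t, 1),
            s_obs=s_obs,
            suitable_area_km2=self.area,
            M=self.M,
            n_observed=self.n_obs,
            settings={
                "iterations": cfg.iterations,
                "burn_in": cfg.burn_in,
                "thin": cfg.thin,
                "kind": cfg.kind,
                "seed": cfg.seed,
                "n_augment": cfg.n_augment,
                "behavioral_response": cfg.behavioral_response,
            },
            accept_rates={
                k: (self.accepts[k] / self.proposals[k] if self.proposals[k] else float("nan"))
                for k in self.accepts
            },
            state_space=self.ss,
            traps=self.traps,
            history=self.history,
        )


def pixel_density_map(posterior: SECRPosterior, per_area: bool = False) -> np.ndarray:
    """Mean included-center count per state-space pixel.

    The total over pixels equals the posterior mean of N exactly. With
    ``per_area`` the counts are divided by the pixel area (density scale).
    """
    if posterior.pixel_mean is None or posterior.state_space is None:
        raise ConsistencyError("posterior does not retain per-pixel counts")
    out = posterior.pixel_mean.copy()
    if per_area:
        out = out / posterior.state_space.pixel_area_km2
    return out


def buffer_sensitivity(
    history: CaptureHistory,
    traps: TrapArray,
    buffers_m,
    pixel_area_km2: float,
    config: FitConfig,
) -> list[dict[str, float]]:
    """Re-fit at increasing buffers; report the density trajectory.

    Supports the preliminary check that density estimates stabilize before
    the chosen buffer distance.
    """
    rows = []
    for b in buffers_m:
        ss = build_state_space(traps, b, pixel_area_km2)
        post = fit_secr(history, traps, ss, config)
        rows.append(
            {
                "buffer_m": float(b),
                "density_mean": float(post.density.mean()),
                "N_mean": float(post.N.mean()),
                "suitable_area_km2": ss.suitable_area_km2,
            }
        )
    return rows


def prior_sensitivity(
    history: CaptureHistory,
    traps: TrapArray,
    state_space: StateSpace,
    config: FitConfig,
    lam0_maxes=None,
    sigma_maxes=None,
) -> list[dict[str, float]]:
    """Re-fit under alternative uniform-prior upper bounds.

    Reports how the density posterior shifts as the lam0/sigma prior
    ranges change — a quick check that the bounds are not informative.
    """
    from dataclasses import replace as _replace

    rows = []
    for lam0_max in lam0_maxes or [config.lam0_max]:
        for sigma_max in sigma_maxes or [config.sigma_max]:
            cfg = _replace(config, lam0_max=lam0_max, sigma_max=sigma_max)
            post = fit_secr(history, traps, state_space, cfg)
            rows.append(
                {
                    "lam0_max": float(lam0_max),
                    "sigma_max": float(sigma_max) if sigma_max is not None else float("nan"),
                    "density_mean": float(post.density.mean()),
                    "lam0_mean": float(post.lam0.mean()),
                    "sigma_mean": float(post.sigma.mean()),
                }
            )
    return rows
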