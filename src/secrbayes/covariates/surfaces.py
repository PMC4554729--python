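"""Per-pixel covariate surfaces and the SECR abundance response."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ..errors import ConsistencyError
from ..secr.sampler import SECRPosterior

__all__ = ["pixel_mean_abundance", "standardize", "unstandardize", "CovariateSurface"]


def pixel_mean_abundance(posterior: SECRPosterior) -> np.ndarray:
    """Mean over MCMC iterations of the per-pixel included-center count.

    The regression response: a non-integer "mean abundance" per pixel whose
    total equals the posterior mean of N.
    """
    if posterior.pixel_mean is None:
        raise ConsistencyError("posterior does not retain per-pixel counts")
    return posterior.pixel_mean.copy()


def standardize(values) -> tuple[np.ndarray, float, float]:
    """Center and scale to mean 0, sd 1; returns (scaled, mean, sd)."""
    v = np.asarray(values, dtype=float)
    mean = float(np.nanmean(v))
    sd = float(np.nanstd(v, ddof=1))
    if sd == 0.0:
        raise ConsistencyError("cannot standardize a constant column")
    return (v - mean) / sd, mean, sd


def unstandardize(scaled, mean: float, sd: float) -> np.ndarray:
    return np.asarray(scaled, dtype=float) * sd + mean


@dataclass(frozen=True)
class CovariateSurface:
    """Per-pixel covariate values on (a subset of) the state-space grid."""

    table: pd.DataFrame  # columns: x, y, prey, grazing, slope_sd
    standardized: bool = False

    _COVS = ("prey", "grazing", "slope_sd")

    def __post_init__(self) -> None:
        missing = [c for c in ("x", "y", *self._COVS) if c not in self.table.columns]
        if missing:
            raise ConsistencyError(f"surface table missing columns {missing}")
        if self.standardized and self.table[list(self._COVS)].isna().any().any():
            raise ConsistencyError("standardized surface contains missing values")

    def standardize(self) -> "CovariateSurface":
        if self.standardized:
            return self
        t = self.table.copy()
        for c in self._COVS:
            t[c], _, _ = standardize(t[c].to_numpy())
        return replace(self, table=t, standardized=True)

    def design_matrix(self, covariates) -> np.ndarray:
        """Intercept + the named covariate columns, in the given order."""
        cols = [np.ones(len(self.table))]
        cols += [self.table[c].to_numpy() for c in covariates]
        return np.column_stack(cols)
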