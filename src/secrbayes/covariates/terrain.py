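"""Slope variability from a gridded digital elevation model."""

from __future__ import annotations

import numpy as np

from ..errors import ConsistencyError
from ..state_space import StateSpace

__all__ = ["slope_degrees", "slope_sd_surface"]


def slope_degrees(elevation: np.ndarray, spacing_m: float) -> np.ndarray:
    """Per-cell slope (degrees) by central finite differences."""
    elev = np.asarray(elevation, dtype=float)
    gx, gy = np.gradient(elev, spacing_m)
    return np.degrees(np.arctan(np.hypot(gx, gy)))


def slope_sd_surface(
    elevation: np.ndarray,
    dem_origin: tuple[float, float],
    dem_spacing_m: float,
    state_space: StateSpace,
    ddof: int = 1,
) -> np.ndarray:
    """Standard deviation of slope per state-space pixel.

    ``dem_origin`` is the lower-left corner of the DEM; cell (i, j) is
    centered at origin + (i + 0.5, j + 0.5) * spacing (x indexes the first
    axis). The DEM must be finer than the pixel grid. Pixels holding fewer
    than two DEM cells are flagged missing (NaN).
    """
    if dem_spacing_m >= state_space.spacing_m:
        raise ConsistencyError("DEM must be finer than the state-space pixels")
    slope = slope_degrees(elevation, dem_spacing_m)
    nx_dem, ny_dem = slope.shape
    cx = dem_origin[0] + (np.arange(nx_dem) + 0.5) * dem_spacing_m
    cy = dem_origin[1] + (np.arange(ny_dem) + 0.5) * dem_spacing_m

    # pixel-grid origin recovered from any stored pixel center
    s = state_space.spacing_m
    x0 = float(state_space.x[0] - (state_space.ix[0] + 0.5) * s)
    y0 = float(state_space.y[0] - (state_space.iy[0] + 0.5) * s)
    gx = np.floor((cx - x0) / s).astype(np.int64)
    gy = np.floor((cy - y0) / s).astype(np.int64)

    lookup = np.full((state_space.nx, state_space.ny), -1, dtype=np.int64)
    lookup[state_space.ix, state_space.iy] = np.arange(state_space.n_pixels)

    gxm, gym = np.meshgrid(gx, gy, indexing="ij")
    valid = (gxm >= 0) & (gxm < state_space.nx) & (gym >= 0) & (gym < state_space.ny)
    pix = np.full(slope.shape, -1, dtype=np.int64)
    pix[valid] = lookup[gxm[valid], gym[valid]]
    inside = pix >= 0

    n = state_space.n_pixels
    counts = np.bincount(pix[inside], minlength=n).astype(float)
    sums = np.bincount(pix[inside], weights=slope[inside], minlength=n)
    sumsq = np.bincount(pix[inside], weights=slope[inside] ** 2, minlength=n)
    out = np.full(n, np.nan)
    ok = counts >= 2
    mean = sums[ok] / counts[ok]
    ss = sumsq[ok] - counts[ok] * mean**2
    denom = counts[ok] - ddof if ddof else counts[ok]
    out[ok] = np.sqrt(np.maximum(ss, 0.0) / denom)
    return out
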