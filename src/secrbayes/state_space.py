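"""Buffered, habitat-masked pixel grid of potential activity centers.

The state space is a regular point grid (spacing = sqrt(pixel area))
covering the trap bounding box expanded by a buffer; a pixel belongs to the
state space iff its center lies within the buffer distance of the nearest
trap. Habitat suitability is a per-pixel flag applied on top.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import TrapArray
from .errors import ConsistencyError, DomainError, FormatError

__all__ = [
    "StateSpace",
    "build_state_space",
    "apply_habitat_mask",
    "read_state_space",
    "write_state_space",
]


@dataclass(frozen=True)
class StateSpace:
    """Pixel centers within the buffer, with suitability flags.

    ``ix``/``iy`` are integer grid coordinates of each pixel (used by the
    MCMC sampler for neighborhood proposals); ``nx``/``ny`` span the full
    buffered rectangle even though out-of-buffer pixels are not stored.
    """

    x: np.ndarray
    y: np.ndarray
    ix: np.ndarray
    iy: np.ndarray
    nx: int
    ny: int
    pixel_area_km2: float
    suitable: np.ndarray  # bool per stored pixel
    buffer_m: float

    def __post_init__(self) -> None:
        for name in ("x", "y"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("ix", "iy"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        object.__setattr__(self, "suitable", np.asarray(self.suitable, dtype=bool))
        n = self.x.shape[0]
        if not (self.y.shape[0] == self.ix.shape[0] == self.iy.shape[0] == n):
            raise ConsistencyError("state-space arrays have mismatched lengths")
        if self.suitable.shape[0] != n:
            raise ConsistencyError("suitability flags do not match pixel count")
        if n == 0 or not self.suitable.any():
            raise ConsistencyError("state space has no suitable pixels")

    @property
    def n_pixels(self) -> int:
        return self.x.shape[0]

    @property
    def spacing_m(self) -> float:
        return float(np.sqrt(self.pixel_area_km2) * 1000.0)

    @property
    def suitable_area_km2(self) -> float:
        return float(self.pixel_area_km2 * self.suitable.sum())

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def grid_lookup(self) -> np.ndarray:
        """(nx, ny) array mapping grid coords to pixel index, -1 elsewhere.

        Unsuitable pixels also map to -1: the lookup serves the sampler,
        whose activity centers live on suitable pixels only.
        """
        lookup = np.full((self.nx, self.ny), -1, dtype=np.int64)
        keep = self.suitable
        lookup[self.ix[keep], self.iy[keep]] = np.flatnonzero(keep)
        return lookup


def build_state_space(
    traps: TrapArray, buffer_m: float, pixel_area_km2: float
) -> StateSpace:
    """Lay a regular pixel grid over the buffered trap bounding box.

    All pixels start suitable; apply_habitat_mask() refines them.
    """
    if buffer_m <= 0:
        raise DomainError("buffer_m must be positive")
    if pixel_area_km2 <= 0:
        raise DomainError("pixel_area_km2 must be positive")
    if traps.n_traps == 0:
        raise DomainError("state space requires at least one trap")

    spacing = float(np.sqrt(pixel_area_km2) * 1000.0)
    x0, x1 = traps.x.min() - buffer_m, traps.x.max() + buffer_m
    y0, y1 = traps.y.min() - buffer_m, traps.y.max() + buffer_m
    nx = max(int(np.ceil((x1 - x0) / spacing)), 1)
    ny = max(int(np.ceil((y1 - y0) / spacing)), 1)
    gx = x0 + (np.arange(nx) + 0.5) * spacing
    gy = y0 + (np.arange(ny) + 0.5) * spacing
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = np.meshgrid(gx, gy, indexing="ij")
    centers = np.column_stack([cx.ravel(), cy.ravel()])

    d = cdist(centers, traps.coords()).min(axis=1)
    inside = d <= buffer_m
    if not inside.any():
        # A buffer smaller than half a pixel spacing can miss every center;
        # fall back to each trap's nearest pixel so the limit case holds.
        nearest = cdist(traps.coords(), centers).argmin(axis=1)
        inside = np.zeros(centers.shape[0], dtype=bool)
        inside[nearest] = True
    return StateSpace(
        x=centers[inside, 0],
        y=centers[inside, 1],
        ix=ix.ravel()[inside],
        iy=iy.ravel()[inside],
        nx=nx,
        ny=ny,
        pixel_area_km2=pixel_area_km2,
        suitable=np.ones(int(inside.sum()), dtype=bool),
        buffer_m=float(buffer_m),
    )


def apply_habitat_mask(state_space: StateSpace, mask_flags) -> StateSpace:
    """Intersect current suitability with a habitat mask (1 = suitable)."""
    mask = np.asarray(mask_flags, dtype=bool)
    if mask.shape[0] != state_space.n_pixels:
        raise ConsistencyError(
            f"mask length {mask.shape[0]} != {state_space.n_pixels} pixels"
        )
    new_suitable = state_space.suitable & mask
    if not new_suitable.any():
        raise ConsistencyError("habitat mask leaves no suitable pixels")
    return replace(state_space, suitable=new_suitable)


def read_state_space(
    path, pixel_area_km2: float, buffer_m: float = float("nan")
) -> StateSpace:
    """Read the X, Y, HABITAT CSV dialect into a StateSpace.

    Grid indices are reconstructed from the coordinates, which must lie on
    a regular grid with spacing sqrt(pixel_area_km2).
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip().upper() for c in header[:3]] != ["X", "Y", "HABITAT"]:
            raise FormatError(f"{path}: header must be X, Y, HABITAT")
        xs, ys, hab = [], [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                xs.append(float(row[0]))
                ys.append(float(row[1]))
                hab.append(int(row[2]))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    x = np.array(xs)
    y = np.array(ys)
    spacing = float(np.sqrt(pixel_area_km2) * 1000.0)
    ix = np.rint((x - x.min()) / spacing).astype(np.int64)
    iy = np.rint((y - y.min()) / spacing).astype(np.int64)
    if len({(a, b) for a, b in zip(ix, iy)}) != len(xs):
        raise FormatError(f"{path}: duplicate pixel centers")
    return StateSpace(
        x=x,
        y=y,
        ix=ix,
        iy=iy,
        nx=int(ix.max()) + 1,
        ny=int(iy.max()) + 1,
        pixel_area_km2=pixel_area_km2,
        suitable=np.array(hab, dtype=bool),
        buffer_m=buffer_m,
    )


def write_state_space(path, state_space: StateSpace) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["X", "Y", "HABITAT"])
        for xi, yi, si in zip(state_space.x, state_space.y, state_space.suitable):
            writer.writerow([repr(float(xi)), repr(float(yi)), int(si)])
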