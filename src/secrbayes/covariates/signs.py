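"""Sign-survey cells and presence indices.

A survey cell is walked as a set of 250 m transect segments; each segment
records presence/absence of prey sign and of livestock-grazing sign. The
per-cell index of either covariate is the proportion of positive segments.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

from ..errors import ConsistencyError, FormatError

__all__ = ["SignSurvey", "sign_index", "read_sign_survey", "write_sign_survey"]


@dataclass(frozen=True)
class SignSurvey:
    cell_id: str
    x: float  # cell centroid, projected meters
    y: float
    n_segments: int
    n_prey_positive: int
    n_grazing_positive: int

    def __post_init__(self) -> None:
        if self.n_segments <= 0:
            raise ConsistencyError(f"cell {self.cell_id}: n_segments must be positive")
        for name in ("n_prey_positive", "n_grazing_positive"):
            v = getattr(self, name)
            if not 0 <= v <= self.n_segments:
                raise ConsistencyError(
                    f"cell {self.cell_id}: {name}={v} outside [0, {self.n_segments}]"
                )


def sign_index(surveys: Sequence[SignSurvey]) -> dict[str, dict[str, float]]:
    """Per-cell proportion of positive segments, for prey and grazing.

    Cells with zero surveyed segments (unreachable through the SignSurvey
    type, guarded anyway) are flagged missing as NaN rather than zero.
    """
    out: dict[str, dict[str, float]] = {}
    for s in surveys:
        if s.n_segments <= 0:
            out[s.cell_id] = {"prey": float("nan"), "grazing": float("nan")}
            continue
        out[s.cell_id] = {
            "prey": s.n_prey_positive / s.n_segments,
            "grazing": s.n_grazing_positive / s.n_segments,
        }
    return out


def read_sign_survey(path) -> list[SignSurvey]:
    """CELL_ID, X, Y, N_SEGMENTS, PREY_POS, GRAZING_POS dialect."""
    expected = ["CELL_ID", "X", "Y", "N_SEGMENTS", "PREY_POS", "GRAZING_POS"]
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in expected if c not in (reader.fieldnames or ())]
        if missing:
            raise FormatError(f"{path}: missing columns {', '.join(missing)}")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            try:
                rows.append(
                    SignSurvey(
                        cell_id=row["CELL_ID"].strip(),
                        x=float(row["X"]),
                        y=float(row["Y"]),
                        n_segments=int(row["N_SEGMENTS"]),
                        n_prey_positive=int(row["PREY_POS"]),
                        n_grazing_positive=int(row["GRAZING_POS"]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return rows


def write_sign_survey(path, surveys: Iterable[SignSurvey]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["CELL_ID", "X", "Y", "N_SEGMENTS", "PREY_POS", "GRAZING_POS"])
        for s in surveys:
            writer.writerow(
                [s.cell_id, repr(s.x), repr(s.y), s.n_segments, s.n_prey_positive, s.n_grazing_positive]
            )
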