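"""Capture-record and trap-deployment data structures.

Holds the tabular inputs of a camera-trap study (trap coordinates with
per-occasion activity flags, time-stamped capture records), the filtering
rules that turn raw records into analysable ones, construction of the
binary individual x trap x occasion capture history, and the classical
descriptive summaries: capture success per 100 trap-days, the
capture-frequency distribution, and the mean maximum distance moved (MMDM).

Coordinates are projected meters throughout; distances are Euclidean.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConsistencyError, DomainError, FormatError

__all__ = [
    "TrapArray",
    "CaptureRecord",
    "CaptureHistory",
    "MovementSummary",
    "OccasionCalendar",
    "DiscardLog",
    "read_capture_records",
    "write_capture_records",
    "read_trap_deployment",
    "write_trap_deployment",
    "filter_capture_records",
    "build_capture_history",
    "capture_success",
    "capture_frequency",
    "mmdm",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrapArray:
    """Trap locations (m) plus a traps x occasions binary activity matrix."""

    trap_ids: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray
    activity: np.ndarray  # shape (n_traps, n_occasions), entries in {0, 1}

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        activity = np.asarray(self.activity)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "activity", activity)
        if len(self.trap_ids) != len(set(self.trap_ids)):
            raise ConsistencyError("trap_ids are not unique")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ConsistencyError("trap coordinates must be finite")
        if x.shape != y.shape or x.shape[0] != len(self.trap_ids):
            raise ConsistencyError("coordinate arrays do not match trap_ids")
        if activity.ndim != 2 or activity.shape[0] != len(self.trap_ids):
            raise ConsistencyError("activity matrix must be traps x occasions")
        if not np.isin(activity, (0, 1)).all():
            raise ConsistencyError("activity entries must be 0 or 1")

    @property
    def n_traps(self) -> int:
        return len(self.trap_ids)

    @property
    def n_occasions(self) -> int:
        return self.activity.shape[1]

    @property
    def trap_days(self) -> int:
        """Total sampling effort: one trap active for one occasion."""
        return int(self.activity.sum())

    def index_of(self, trap_id: str) -> int:
        try:
            return self.trap_ids.index(trap_id)
        except ValueError:
            raise ConsistencyError(f"unknown trap id {trap_id!r}") from None

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class CaptureRecord:
    individual_id: str
    trap_id: str
    timestamp: datetime | None = None
    occasion: int | None = None  # used by the occasion-numbered dialect
    usable: bool = True

    def __post_init__(self) -> None:
        if self.timestamp is None and self.occasion is None:
            raise ConsistencyError(
                "capture record needs a timestamp or an occasion number"
            )


@dataclass(frozen=True)
class OccasionCalendar:
    """Maps calendar days to occasion indices 0..n_occasions-1.

    An occasion is a midnight-to-midnight local day; ``start`` is the day
    of occasion 0.
    """

    start: date
    n_occasions: int

    def occasion_of(self, when: datetime | date) -> int:
        d = when.date() if isinstance(when, datetime) else when
        k = (d - self.start).days
        if not 0 <= k < self.n_occasions:
            raise ConsistencyError(
                f"date {d.isoformat()} outside the {self.n_occasions}-occasion calendar"
            )
        return k


@dataclass(frozen=True)
class CaptureHistory:
    """Binary tensor y[i, j, k]: individual i seen at trap j on occasion k."""

    y: np.ndarray
    individual_ids: tuple[str, ...]
    trap_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=np.int8)
        object.__setattr__(self, "y", y)
        if y.ndim != 3:
            raise ConsistencyError("capture history must be 3-dimensional")
        if y.shape[0] != len(self.individual_ids) or y.shape[1] != len(self.trap_ids):
            raise ConsistencyError("capture history dimensions do not match id lists")
        if not np.isin(y, (0, 1)).all():
            raise ConsistencyError("capture history entries must be 0 or 1")
        if y.shape[0] == 0:
            raise ConsistencyError("capture history contains no individuals")
        if (y.sum(axis=(1, 2)) == 0).any():
            raise ConsistencyError("every individual must have at least one capture")

    @property
    def n_individuals(self) -> int:
        return self.y.shape[0]

    @property
    def n_traps(self) -> int:
        return self.y.shape[1]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[2]

    @property
    def n_captures(self) -> int:
        return int(self.y.sum())

    def validate_against(self, traps: TrapArray) -> None:
        """Check dimensional agreement and that captures imply active traps."""
        if self.n_traps != traps.n_traps or self.n_occasions != traps.n_occasions:
            raise ConsistencyError("capture history does not match trap array shape")
        bad = self.y.any(axis=0) & (traps.activity == 0)
        if bad.any():
            j, k = map(int, np.argwhere(bad)[0])
            raise ConsistencyError(
                f"capture at inactive trap-occasion (trap {traps.trap_ids[j]}, occasion {k})"
            )


@dataclass(frozen=True)
class MovementSummary:
    """MMDM and dispersion from individuals recaptured at distinct traps.

    ``sd`` is the sample standard deviation of per-individual maxima and
    ``se`` is sd/sqrt(n); both are reported because published dispersion
    figures are frequently ambiguous between the two.
    """

    per_individual: Mapping[str, float]  # max distance moved, meters
    mmdm: float
    half_mmdm: float
    sd: float
    se: float
    n: int

    @property
    def defined(self) -> bool:
        return self.n > 0

    @staticmethod
    def undefined() -> "MovementSummary":
        nan = float("nan")
        return MovementSummary({}, nan, nan, nan, nan, 0)


@dataclass
class DiscardLog:
    """One entry per removed record, with a machine-readable reason."""

    entries: list[tuple[CaptureRecord, str]] = field(default_factory=list)

    def add(self, record: CaptureRecord, reason: str) -> None:
        self.entries.append((record, reason))

    def reasons(self) -> list[str]:
        return [r for _, r in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def read_capture_records(path) -> list[CaptureRecord]:
    """Read the animal-capture CSV dialect.

    Expected columns: LOC_ID, ANIMAL_ID and either TIMESTAMP (ISO 8601) or
    SO (1-based occasion number). Malformed rows raise a FormatError that
    names the offending line.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = set(reader.fieldnames or ())
        for required in ("LOC_ID", "ANIMAL_ID"):
            if required not in cols:
                raise FormatError(f"{path}: missing required column {required}")
        if "TIMESTAMP" not in cols and "SO" not in cols:
            raise FormatError(f"{path}: need a TIMESTAMP or SO column")
        timestamped = "TIMESTAMP" in cols

        records: list[CaptureRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                if timestamped:
                    ts = datetime.fromisoformat(row["TIMESTAMP"].strip())
                    rec = CaptureRecord(
                        individual_id=row["ANIMAL_ID"].strip(),
                        trap_id=row["LOC_ID"].strip(),
                        timestamp=ts,
                    )
                else:
                    rec = CaptureRecord(
                        individual_id=row["ANIMAL_ID"].strip(),
                        trap_id=row["LOC_ID"].strip(),
                        occasion=int(row["SO"]) - 1,
                    )
            except (ValueError, TypeError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_capture_records(path, records: Iterable[CaptureRecord]) -> None:
    records = list(records)
    timestamped = all(r.timestamp is not None for r in records)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if timestamped:
            writer.writerow(["LOC_ID", "ANIMAL_ID", "TIMESTAMP"])
            for r in records:
                writer.writerow([r.trap_id, r.individual_id, r.timestamp.isoformat()])
        else:
            writer.writerow(["LOC_ID", "ANIMAL_ID", "SO"])
            for r in records:
                writer.writerow([r.trap_id, r.individual_id, r.occasion + 1])


def read_trap_deployment(path) -> TrapArray:
    """Read the trap-deployment CSV dialect: LOC_ID, X, Y, then K 1/0 flags."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or len(header) < 4:
            raise FormatError(f"{path}: expected LOC_ID, X, Y and activity columns")
        if [c.strip().upper() for c in header[:3]] != ["LOC_ID", "X", "Y"]:
            raise FormatError(f"{path}: header must start with LOC_ID, X, Y")
        ids: list[str] = []
        xs: list[float] = []
        ys: list[float] = []
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                ids.append(row[0].strip())
                xs.append(float(row[1]))
                ys.append(float(row[2]))
                rows.append([int(v) for v in row[3:]])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if len(rows[-1]) != len(header) - 3:
                raise FormatError(f"{path}: line {lineno}: wrong number of activity flags")
    return TrapArray(tuple(ids), np.array(xs), np.array(ys), np.array(rows))


def write_trap_deployment(path, traps: TrapArray) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["LOC_ID", "X", "Y"] + [f"D{k + 1}" for k in range(traps.n_occasions)]
        )
        for j, tid in enumerate(traps.trap_ids):
            writer.writerow(
                [tid, repr(float(traps.x[j])), repr(float(traps.y[j]))]
                + traps.activity[j].astype(int).tolist()
            )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_capture_records(
    records: Sequence[CaptureRecord],
    dedup_window_hours: float = 6.0,
    deployment: Mapping[str, tuple[datetime, datetime]] | None = None,
) -> tuple[list[CaptureRecord], DiscardLog]:
    """Apply the two standard discard rules to raw capture records.

    1. Same individual at the same trap within ``dedup_window_hours`` of an
       already-kept capture: the later capture is discarded ("dedup").
    2. Capture on an incomplete first/last deployment day of its trap, as
       derived from ``deployment`` (trap_id -> (deployed, picked_up)
       datetimes): discarded ("incomplete_day"). A day is incomplete when
       deployment started after midnight (first day) or ended before the
       following midnight (last day).

    Returns the kept records (chronological per individual/trap pair) and a
    DiscardLog with a reason per removal. Deduplication is greedy from the
    earliest capture onward, which makes the filter idempotent.
    """
    if dedup_window_hours <= 0:
        raise DomainError("dedup_window_hours must be positive")
    log = DiscardLog()

    survivors: list[CaptureRecord] = []
    if deployment is not None:
        for rec in records:
            window = deployment.get(rec.trap_id)
            if window is not None and rec.timestamp is not None:
                if _on_incomplete_day(rec.timestamp, *window):
                    log.add(rec, "incomplete_day")
                    continue
            survivors.append(rec)
    else:
        survivors = list(records)

    window_delta = timedelta(hours=dedup_window_hours)
    kept: list[CaptureRecord] = []
    groups: dict[tuple[str, str], list[CaptureRecord]] = {}
    untimed: list[CaptureRecord] = []
    for rec in survivors:
        if rec.timestamp is None:
            untimed.append(rec)  # occasion-numbered dialect: nothing to dedup
        else:
            groups.setdefault((rec.individual_id, rec.trap_id), []).append(rec)
    for group in groups.values():
        group.sort(key=lambda r: r.timestamp)
        last_kept: datetime | None = None
        for rec in group:
            if last_kept is not None and rec.timestamp - last_kept < window_delta:
                log.add(rec, "dedup")
            else:
                kept.append(rec)
                last_kept = rec.timestamp
    kept.extend(untimed)
    return kept, log


def _on_incomplete_day(ts: datetime, deployed: datetime, picked_up: datetime) -> bool:
    day = ts.date()
    first_partial = deployed.time() != time.min and day == deployed.date()
    last_partial = picked_up.time() != time.min and day == picked_up.date()
    return first_partial or last_partial


# ---------------------------------------------------------------------------
# Capture history and summaries
# ---------------------------------------------------------------------------

def build_capture_history(
    records: Sequence[CaptureRecord],
    traps: TrapArray,
    occasion_calendar: OccasionCalendar | None = None,
) -> CaptureHistory:
    """Assemble the binary y[i, j, k] tensor from filtered records.

    Individuals are ordered by sorted id for determinism. Repeated
    same-trap same-occasion captures collapse to a single 1. A record at an
    inactive trap-occasion raises a ConsistencyError naming the record.
    """
    if not records:
        raise ConsistencyError("no capture records: capture history undefined")
    individual_ids = tuple(sorted({r.individual_id for r in records}))
    row = {iid: i for i, iid in enumerate(individual_ids)}
    y = np.zeros((len(individual_ids), traps.n_traps, traps.n_occasions), dtype=np.int8)
    for rec in records:
        j = traps.index_of(rec.trap_id)
        if rec.occasion is not None:
            k = rec.occasion
            if not 0 <= k < traps.n_occasions:
                raise ConsistencyError(f"occasion {k} out of range for {rec}")
        else:
            if occasion_calendar is None:
                raise ConsistencyError(
                    "timestamped records need an occasion calendar"
                )
            k = occasion_calendar.occasion_of(rec.timestamp)
        if traps.activity[j, k] == 0:
            raise ConsistencyError(
                f"record at inactive trap-occasion: {rec} (trap {rec.trap_id}, occasion {k})"
            )
        y[row[rec.individual_id], j, k] = 1
    return CaptureHistory(y, individual_ids, traps.trap_ids)


def capture_success(n_captures: int, trap_days: int) -> float:
    """Captures per 100 trap-days."""
    if trap_days <= 0:
        raise DomainError("trap_days must be positive")
    if n_captures < 0:
        raise DomainError("n_captures must be nonnegative")
    return 100.0 * n_captures / trap_days


def capture_frequency(history: CaptureHistory) -> dict[int, int]:
    """Histogram: number of captures -> number of individuals."""
    per_individual = history.y.sum(axis=(1, 2))
    counts, freqs = np.unique(per_individual, return_counts=True)
    return {int(c): int(f) for c, f in zip(counts, freqs)}


def mmdm(history: CaptureHistory, traps: TrapArray) -> MovementSummary:
    """Mean maximum distance moved over individuals caught at >=2 traps.

    Per contributing individual: the maximum pairwise Euclidean distance
    among the traps where it was captured. Individuals captured at a single
    trap (however many times) do not contribute.
    """
    history.validate_against(traps)
    coords = traps.coords()
    maxima: dict[str, float] = {}
    for i, iid in enumerate(history.individual_ids):
        trap_idx = np.flatnonzero(history.y[i].any(axis=1))
        if len(trap_idx) < 2:
            continue
        pts = coords[trap_idx]
        diff = pts[:, None, :] - pts[None, :, :]
        maxima[iid] = float(np.sqrt((diff**2).sum(axis=-1)).max())
    if not maxima:
        return MovementSummary.undefined()
    values = np.array(list(maxima.values()))
    n = len(values)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return MovementSummary(
        per_individual=maxima,
        mmdm=mean,
        half_mmdm=mean / 2.0,
        sd=sd,
        se=sd / math.sqrt(n),
        n=n,
    )
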