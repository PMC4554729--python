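"""Posterior chain summaries: moments, mode, and HPD intervals."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import DomainError

__all__ = ["PosteriorSummary", "posterior_summary", "hpd_interval", "histogram_mode"]


@dataclass(frozen=True)
class PosteriorSummary:
    mean: float
    sd: float
    median: float
    mode: float
    hpd_lower: float
    hpd_upper: float

    def contains(self, value: float) -> bool:
        return self.hpd_lower <= value <= self.hpd_upper


def hpd_interval(chain, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the sorted samples."""
    x = np.sort(np.asarray(chain, dtype=float))
    n = x.shape[0]
    if n == 0:
        raise DomainError("empty chain")
    m = int(np.ceil(prob * n))
    m = min(max(m, 1), n)
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def histogram_mode(chain) -> float:
    """Midpoint of the highest-count histogram bin, Freedman-Diaconis widths.

    Falls back to the median when the IQR is zero (near-constant chains).
    """
    x = np.asarray(chain, dtype=float)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return float(np.median(x))
    width = 2.0 * iqr / len(x) ** (1.0 / 3.0)
    n_bins = max(int(np.ceil((x.max() - x.min()) / width)), 1)
    counts, edges = np.histogram(x, bins=n_bins)
    b = int(np.argmax(counts))
    return float(0.5 * (edges[b] + edges[b + 1]))


def posterior_summary(chain, prob: float = 0.95, min_length: int = 100) -> PosteriorSummary:
    """Mean, SD, median, histogram mode, and HPD interval of a chain."""
    x = np.asarray(chain, dtype=float)
    if x.ndim != 1:
        raise DomainError("chain must be one-dimensional")
    if x.shape[0] < min_length:
        raise DomainError(f"chain length {x.shape[0]} < required {min_length}")
    lo, hi = hpd_interval(x, prob)
    return PosteriorSummary(
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        median=float(np.median(x)),
        mode=histogram_mode(x),
        hpd_lower=lo,
        hpd_upper=hi,
    )
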