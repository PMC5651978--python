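"""Burst-size statistics of the exit-event stream.

A burst is a maximal run of consecutive exits whose inter-exit gaps are all
below a threshold; its size S is the number of exits in the run.  The
frequency F(S), normalized by the number of pooled runs q, follows an
approximately inverse (power-law-like) relation with S at a bottleneck, which
is assessed by a least-squares line through (log10 S, log10 F(S)/q).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["BurstSeries", "bursts_from_exits", "burst_frequency", "loglog_fit"]


@dataclass(frozen=True)
class BurstSeries:
    """Burst sizes in temporal order with their construction parameters."""

    sizes: tuple[int, ...]
    gap_threshold: float
    q: int = 1

    def __post_init__(self):
        if any(s < 1 for s in self.sizes):
            raise ValueError("burst sizes must be positive")
        if self.q < 1 or self.gap_threshold <= 0.0:
            raise ValueError("q must be >= 1 and gap_threshold positive")

    def frequency(self) -> pd.DataFrame:
        return burst_frequency(self.sizes, self.q)


def bursts_from_exits(exit_times, gap_threshold: float) -> list[int]:
    """Reduce sorted exit times to burst sizes.

    Consecutive exits separated by less than ``gap_threshold`` belong to one
    burst.  An empty input yields an empty list.
    """
    if gap_threshold <= 0.0:
        raise ValueError("gap_threshold must be positive")
    t = np.asarray(exit_times, dtype=float)
    if t.size == 0:
        return []
    if np.any(np.diff(t) < 0.0):
        raise ValueError("exit times must be sorted non-decreasing")
    breaks = np.nonzero(np.diff(t) >= gap_threshold)[0]
    edges = np.concatenate(([0], breaks + 1, [t.size]))
    return list(np.diff(edges).astype(int))


def burst_frequency(sizes, q: int = 1) -> pd.DataFrame:
    """Table of burst size S and normalized frequency F(S)/q (zero-count
    sizes omitted)."""
    if q <= 0:
        raise ValueError("q must be positive")
    sizes = np.asarray(sizes, dtype=int)
    if sizes.size == 0:
        return pd.DataFrame(columns=["size", "freq"]).astype(
            {"size": int, "freq": float}
        )
    uniq, counts = np.unique(sizes, return_counts=True)
    return pd.DataFrame({"size": uniq, "freq": counts / q})


def loglog_fit(table: pd.DataFrame) -> tuple[float, float, float]:
    """Least-squares line through (log10 S, log10 F(S)/q).

    Returns ``(slope, intercept, r_squared)``; requires at least three
    distinct sizes with positive frequency.
    """
    t = table[table["freq"] > 0.0]
    if t["size"].nunique() < 3:
        raise ValueError("log-log fit needs >= 3 distinct burst sizes")
    res = stats.linregress(np.log10(t["size"]), np.log10(t["freq"]))
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
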