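"""Rank-frequency tables and log-log power-law (Zipf) fitting.

A vocabulary obeys a Zipf-like law when word frequency falls as a power
of rank, f_i = beta / r_i**a, i.e. ln f = -a ln r + ln beta.  Following
the standard practice-pattern analysis, the exponent is estimated by
ordinary least squares of ln(frequency) on ln(rank) with natural
logarithms; the fit's slope estimates -a and the Pearson correlation r
of the log-log points is reported alongside (R² is its square, which
coincides with the regression R² for simple OLS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import VocabularyCounts, Word, build_vocabulary

__all__ = [
    "RankFrequencyTable",
    "PowerLawFit",
    "GroupFitSummary",
    "FitError",
    "rank_frequency",
    "fit_power_law",
    "fit_per_group",
]


class FitError(ValueError):
    """Raised when a table has too few qualifying points to fit."""


@dataclass(frozen=True)
class RankFrequencyTable:
    """Rank-ordered (rank, word, frequency) rows.

    Ranks are ordinal 1..N; frequency is non-increasing in rank, with
    ties broken by lexicographic order of the word so tables are
    deterministic functions of the vocabulary.
    """

    rows: tuple[tuple[int, str, int], ...]
    total_tokens: int

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def ranks(self) -> np.ndarray:
        return np.array([r for r, _, _ in self.rows], dtype=float)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([f for _, _, f in self.rows], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["rank", "word", "count"])


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of ln(frequency) on ln(rank).

    ``slope`` estimates -a and ``intercept`` estimates ln(beta) of the
    Zipf-like law.  ``degenerate`` marks zero-variance inputs (all
    frequencies equal), reported as slope 0 with r = 0 rather than an
    error.
    """

    slope: float
    intercept: float
    r: float
    r2: float
    n_points: int
    degenerate: bool = False


@dataclass(frozen=True)
class GroupFitSummary:
    """Per-group fits plus dispersion of slope and correlation across groups."""

    fits: Mapping[str, PowerLawFit]
    excluded: Mapping[str, str] = field(default_factory=dict)

    def _values(self, attr: str) -> np.ndarray:
        return np.array([getattr(f, attr) for f in self.fits.values()])

    def summary(self) -> dict[str, float]:
        slopes = self._values("slope")
        rs = self._values("r")
        return {
            "n_groups": float(len(slopes)),
            "slope_mean": float(slopes.mean()),
            "slope_sd": float(slopes.std(ddof=1)) if len(slopes) > 1 else 0.0,
            "slope_min": float(slopes.min()),
            "slope_max": float(slopes.max()),
            "r_mean": float(rs.mean()),
            "r_sd": float(rs.std(ddof=1)) if len(rs) > 1 else 0.0,
            "r_min": float(rs.min()),
            "r_max": float(rs.max()),
        }


def rank_frequency(v: VocabularyCounts | Mapping[str, int]) -> RankFrequencyTable:
    """Build the rank-frequency table of a vocabulary.

    Words are sorted by descending count, ties by lexicographic word
    order; ranks are ordinal 1..N.  An empty vocabulary yields an empty
    table.
    """
    counts = v.counts if isinstance(v, VocabularyCounts) else v
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = tuple((i + 1, word, int(c)) for i, (word, c) in enumerate(ordered))
    return RankFrequencyTable(rows=rows, total_tokens=sum(counts.values()))


def fit_power_law(t: RankFrequencyTable, min_count: int = 1) -> PowerLawFit:
    """OLS of ln(frequency) on ln(rank) over rows with count >= min_count.

    ``min_count`` exists because finite samples flatten the low-count
    tail; the default fits all observed ranks.
    """
    pairs = [(r, f) for r, _, f in t.rows if f >= min_count]
    if len(pairs) < 2:
        raise FitError(f"need >= 2 rows with count >= {min_count}, have {len(pairs)}")
    x = np.log([r for r, _ in pairs])
    y = np.log([f for _, f in pairs])
    if np.ptp(y) == 0.0:
        # all frequencies equal: slope 0, correlation undefined
        return PowerLawFit(slope=0.0, intercept=float(y[0]), r=0.0, r2=0.0,
                           n_points=len(pairs), degenerate=True)
    res = stats.linregress(x, y)
    return PowerLawFit(slope=float(res.slope), intercept=float(res.intercept),
                       r=float(res.rvalue), r2=float(res.rvalue**2),
                       n_points=len(pairs))


def fit_per_group(words: Iterable[tuple[str, "Word | str"]],
                  min_count: int = 1) -> GroupFitSummary:
    """Independent rank-frequency + power-law fit per group (e.g. per subject).

    Groups that cannot be fitted (fewer than two distinct qualifying
    words, or a degenerate spectrum) are excluded and listed with the
    reason rather than aborting the run.
    """
    streams: dict[str, list] = {}
    for gid, w in words:
        streams.setdefault(str(gid), []).append(w)
    fits: dict[str, PowerLawFit] = {}
    excluded: dict[str, str] = {}
    for gid in sorted(streams):
        table = rank_frequency(build_vocabulary(streams[gid]))
        try:
            fits[gid] = fit_power_law(table, min_count=min_count)
        except FitError as exc:
            excluded[gid] = str(exc)
    return GroupFitSummary(fits=fits, excluded=excluded)


def fits_to_frame(summary: GroupFitSummary,
                  population: PowerLawFit | None = None) -> pd.DataFrame:
    """Tabulate fits as the ``fits.tsv`` layout (group, slope, intercept, r, r2, n)."""
    rows = []
    if population is not None:
        rows.append(("population", population.slope, population.intercept,
                     population.r, population.r2, population.n_points))
    for gid, f in summary.fits.items():
        rows.append((gid, f.slope, f.intercept, f.r, f.r2, f.n_points))
    return pd.DataFrame(rows, columns=["group", "slope", "intercept", "r", "r2", "n"])
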