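"""Fossil range-through diversity and interval diversification rates.

Standing diversity at an instant t is the number of taxa whose
first-last occurrence interval spans t (boundaries inclusive: a species
whose range endpoint equals t counts as extant at t).  Net per-lineage
diversification over an interval is estimated from boundary standing
counts as ln(N_end / N_start) / dt, the standard exponential-growth
estimator; rate series from independent sources (fossil counts,
chronogram lineage counts) are compared by Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tree import Chronogram, ltt

__all__ = [
    "FossilRange",
    "RateSeries",
    "prune_occurrences",
    "standing_diversity",
    "diversity_curve",
    "interval_rates_from_counts",
    "rates_from_standing_counts",
    "timetree_interval_rates",
    "compare_rate_series",
]

INDET_MARKERS = {"", "sp", "sp.", "spp", "spp.", "indet", "indet.", "cf."}


@dataclass(frozen=True)
class FossilRange:
    taxon: str
    first: float  # Ma, oldest occurrence
    last: float  # Ma, youngest occurrence
    species_level: bool = True

    def __post_init__(self):
        if not self.first >= self.last >= 0:
            raise ValueError(f"{self.taxon}: need first >= last >= 0")


@dataclass
class RateSeries:
    """Net diversification rates over contiguous intervals.

    ``boundaries`` are interval edges in Ma, strictly decreasing
    (e.g. 55, 50, ..., 0); ``rates[i]`` covers
    (boundaries[i], boundaries[i+1]).  Missing rates are NaN.
    """

    boundaries: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(np.diff(self.boundaries) >= 0):
            raise ValueError("boundaries must be strictly decreasing in age")
        if len(self.rates) != len(self.boundaries) - 1:
            raise ValueError("need one rate per interval")


def _is_species_level(species) -> bool:
    if species is None or (isinstance(species, float) and np.isnan(species)):
        return False
    return str(species).strip().lower() not in INDET_MARKERS


def prune_occurrences(records: pd.DataFrame) -> list[FossilRange]:
    """Collapse raw occurrence records to per-species ranges.

    ``records`` columns: ``genus``, ``species``, ``first_ma``, ``last_ma``.
    Species-level occurrences are pooled per binomial.  A genus whose
    occurrences are *all* species-indeterminate is kept as one
    pseudo-species spanning those records; a genus with any determinate
    occurrence drops its indeterminate ones.  Records with missing ages
    are skipped (counted in a warning).
    """
    req = {"genus", "species", "first_ma", "last_ma"}
    if not req.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(req)}")
    df = records.copy()
    bad = df["first_ma"].isna() | df["last_ma"].isna()
    if bad.any():
        warnings.warn(f"skipping {int(bad.sum())} records with missing ages")
        df = df[~bad]
    df["_sp_level"] = df["species"].map(_is_species_level)

    ranges = []
    for genus, grp in df.groupby("genus", sort=True):
        determinate = grp[grp["_sp_level"]]
        if len(determinate):
            for sp, sub in determinate.groupby("species", sort=True):
                ranges.append(
                    FossilRange(
                        taxon=f"{genus} {sp}",
                        first=float(sub["first_ma"].max()),
                        last=float(sub["last_ma"].min()),
                    )
                )
        else:  # genus represented only by indeterminate material
            ranges.append(
                FossilRange(
                    taxon=f"{genus} sp.",
                    first=float(grp["first_ma"].max()),
                    last=float(grp["last_ma"].min()),
                    species_level=False,
                )
            )
    return ranges


def standing_diversity(ranges, t: float) -> int:
    """Range-through count of taxa whose (first, last) interval spans t."""
    return sum(1 for r in ranges if r.first >= t >= r.last)


def diversity_curve(ranges, old: float = 66.0, young: float = 0.0, step: float = 1.0):
    """Standing diversity sampled on a regular age grid (old -> young)."""
    ages = np.arange(old, young - step / 2, -step)
    counts = np.array([standing_diversity(ranges, float(t)) for t in ages])
    return ages, counts


def interval_rates_from_counts(n_start: float, n_end: float, dt: float) -> float:
    """ln(N_end / N_start) / dt; NaN when either boundary count is zero."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_start <= 0 or n_end <= 0:
        return float("nan")
    return float(np.log(n_end / n_start) / dt)


def rates_from_standing_counts(ranges, boundaries) -> RateSeries:
    """Fossil net rates from range-through counts at interval boundaries."""
    boundaries = np.asarray(boundaries, dtype=float)
    counts = [standing_diversity(ranges, float(b)) for b in boundaries]
    rates = [
        interval_rates_from_counts(counts[i], counts[i + 1],
                                   boundaries[i] - boundaries[i + 1])
        for i in range(len(boundaries) - 1)
    ]
    return RateSeries(boundaries=boundaries, rates=np.array(rates))


def timetree_interval_rates(tree: Chronogram, boundaries) -> RateSeries:
    """Net rates per interval from a chronogram's lineage counts.

    Boundary lineage counts come from the LTT curve; boundaries older
    than the root get a count of 1 lineage only at exactly the root age
    and a missing rate above it.
    """
    boundaries = np.asarray(boundaries, dtype=float)
    if np.any(np.diff(boundaries) >= 0):
        raise ValueError("boundaries must be sorted old to young (decreasing)")
    curve = ltt(tree)
    root_age = tree.root_age
    counts = np.array(
        [curve.count_at(float(b)) if b <= root_age else np.nan for b in boundaries]
    )
    rates = np.array(
        [
            interval_rates_from_counts(counts[i], counts[i + 1],
                                       boundaries[i] - boundaries[i + 1])
            if np.isfinite(counts[i]) and np.isfinite(counts[i + 1])
            else np.nan
            for i in range(len(boundaries) - 1)
        ]
    )
    return RateSeries(boundaries=boundaries, rates=rates)


def compare_rate_series(a, b, method: str = "pearson") -> float:
    """Correlation between two rate series (pairwise-complete).

    Accepts :class:`RateSeries` or plain arrays.  Returns NaN when either
    series has zero variance after pairwise deletion.
    """
    x = np.asarray(a.rates if isinstance(a, RateSeries) else a, dtype=float)
    y = np.asarray(b.rates if isinstance(b, RateSeries) else b, dtype=float)
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")
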