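"""Bayesian classification of medicinal over- and under-utilized plant
families.

Model
-----
For a family with ``n`` taxa in a regional reference set (flora database or
traditional-medicines database) of which ``x`` are medicinally reported, the
use proportion ``p`` gets a uniform Beta(1, 1) prior, so the posterior is

    p | x, n  ~  Beta(x + 1, n - x + 1).

The 95% credible interval is the pair of 2.5% ("inferior") and 97.5%
("superior") posterior quantiles.  A family is *overused* when its inferior
bound lies strictly above the superior bound of the interval computed from
the regional totals, *underused* when its superior bound lies strictly
below the regional inferior bound, and *neutral* otherwise.  The margin
("difference to interval") quantifies the gap to the nearest total bound
and is always computed on unrounded quantiles.

No multiple-testing correction is applied; reports carry the number of
families tested so family-wise error can be judged by the reader.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as _beta

__all__ = [
    "FamilyCount", "CredibleInterval", "UtilizationResult",
    "beta_credible_interval", "pooled_total", "classify_utilization",
    "margin", "rank_families", "results_to_frame",
    "OVERUSED", "UNDERUSED", "NEUTRAL", "UNANALYZABLE",
]

OVERUSED = "overused"
UNDERUSED = "underused"
NEUTRAL = "neutral"
UNANALYZABLE = "unanalyzable"


@dataclass(frozen=True)
class FamilyCount:
    """Reference-set size and medicinally used taxa for one family."""
    family: str
    n_reference: int
    x_used: int

    def __post_init__(self):
        if self.n_reference < 0 or self.x_used < 0:
            raise ValueError(f"{self.family}: negative counts")


@dataclass(frozen=True)
class CredibleInterval:
    inferior: float
    superior: float
    level: float = 0.95

    def __post_init__(self):
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if not self.inferior < self.superior:
            raise ValueError("inferior must be below superior")


@dataclass(frozen=True)
class UtilizationResult:
    family: str
    counts: FamilyCount
    interval: CredibleInterval | None
    total_interval: CredibleInterval
    category: str
    margin: float


def beta_credible_interval(x: int, n: int, level: float = 0.95) -> CredibleInterval:
    """Equal-tailed credible interval of the Beta(x+1, n-x+1) posterior.

    ``x`` successes out of ``n`` trials under a uniform prior; quantile
    accuracy is that of the regularized incomplete beta inverse (well below
    1e-8).
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= x <= n:
        raise ValueError(f"x must satisfy 0 <= x <= n, got x={x}, n={n}")
    tail = (1.0 - level) / 2.0
    lo, hi = _beta.ppf([tail, 1.0 - tail], x + 1, n - x + 1)
    return CredibleInterval(float(lo), float(hi), level)


def pooled_total(table: Sequence[FamilyCount]) -> FamilyCount:
    """Sum of reference and used counts over a family table.

    The published "Total" rows use whole-dataset counts which may exceed the
    sum over the listed families; callers analysing printed tables should
    pass their explicit totals instead.
    """
    table = list(table)
    if not table:
        raise ValueError("empty family table")
    return FamilyCount("Total",
                       sum(f.n_reference for f in table),
                       sum(f.x_used for f in table))


def margin(family_interval: CredibleInterval,
           total_interval: CredibleInterval, category: str) -> float:
    """Signed gap between a family interval and the regional-total interval.

    overused:  family.inferior - total.superior   (> 0)
    underused: family.superior - total.inferior   (< 0)
    neutral:   the larger of the two shortfalls, a non-positive distance
               to significance.
    """
    if family_interval.level != total_interval.level:
        raise ValueError("intervals computed at different levels")
    f, t = family_interval, total_interval
    if category == OVERUSED:
        return f.inferior - t.superior
    if category == UNDERUSED:
        return f.superior - t.inferior
    return max(f.inferior - t.superior, t.inferior - f.superior)


def _categorize(f: CredibleInterval, t: CredibleInterval) -> str:
    if f.inferior > t.superior:
        return OVERUSED
    if f.superior < t.inferior:
        return UNDERUSED
    return NEUTRAL


def classify_utilization(table: Iterable[FamilyCount], total: FamilyCount,
                         level: float = 0.95) -> list[UtilizationResult]:
    """Classify every family against the regional total interval.

    Families absent from the reference set (n=0) are returned as
    'unanalyzable' rather than silently dropped, so harmonization gaps stay
    visible.  Inconsistent rows (x > n) raise with the family name attached.
    """
    t_int = beta_credible_interval(total.x_used, total.n_reference, level)
    results = []
    for fc in table:
        if fc.n_reference == 0:
            results.append(UtilizationResult(fc.family, fc, None, t_int,
                                             UNANALYZABLE, float("nan")))
            continue
        try:
            f_int = beta_credible_interval(fc.x_used, fc.n_reference, level)
        except ValueError as err:
            raise ValueError(f"{fc.family}: {err}") from None
        cat = _categorize(f_int, t_int)
        results.append(UtilizationResult(fc.family, fc, f_int, t_int, cat,
                                         margin(f_int, t_int, cat)))
    return results


_CATEGORY_ORDER = {OVERUSED: 0, UNDERUSED: 1, NEUTRAL: 2, UNANALYZABLE: 3}


def rank_families(results: Sequence[UtilizationResult]) -> list[UtilizationResult]:
    """Deterministic ranking: overused by margin descending, underused by
    margin ascending (most negative first), neutral by distance to
    significance (closest first); ties broken lexicographically."""
    def sort_key(r: UtilizationResult):
        if r.category == OVERUSED:
            inner = -r.margin
        elif r.category == UNDERUSED:
            inner = r.margin
        elif r.category == NEUTRAL:
            inner = -r.margin
        else:
            inner = 0.0
        return (_CATEGORY_ORDER[r.category], inner, r.family)
    return sorted(results, key=sort_key)


def results_to_frame(results: Sequence[UtilizationResult],
                     decimals: int = 3) -> pd.DataFrame:
    """Tabular report mirroring the published utilization tables: display
    columns rounded half-even to ``decimals`` plus full-precision columns."""
    rows = []
    n_tested = sum(1 for r in results if r.category != UNANALYZABLE)
    for r in results:
        lo = r.interval.inferior if r.interval else np.nan
        hi = r.interval.superior if r.interval else np.nan
        rows.append({
            "family": r.family,
            "n_reference": r.counts.n_reference,
            "x_used": r.counts.x_used,
            "inferior": np.round(lo, decimals),
            "superior": np.round(hi, decimals),
            "margin": np.round(r.margin, decimals),
            "category": r.category,
            "inferior_full": lo,
            "superior_full": hi,
            "margin_full": r.margin,
            "n_families_tested": n_tested,
        })
    return pd.DataFrame(rows)
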