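"""Descriptive statistics over coded survey records: per-area usage
profiles, ailment rankings, genus citation counts, shared/unique taxa,
cross-region genus overlap and the literature novelty screen.

Counting units
--------------
A record contributes once per ailment code to the ailment profile (a report
treating fever and malaria counts under both), and once per
'|'-alternative to the part/preparation/route profiles (a remedy with two
alternative preparations counts each).  The unit is switchable to
per-record counting via ``unit='records'`` since the published figures do
not state theirs.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .survey import SurveyRecord, UseEvent, normalize_name

__all__ = [
    "FrequencyProfile", "OverlapSummary", "usage_frequency",
    "top_conditions", "genus_citation_counts", "shared_taxa",
    "region_overlap", "combined_genus_table", "novelty_screen",
]

_DIMENSIONS = ("part", "preparation", "route", "ailment")
_FIELD = {"part": "part_code", "preparation": "prep_code",
          "route": "route_code", "ailment": "ailment_code"}


@dataclass(frozen=True)
class FrequencyProfile:
    """Counts and percentages of code usage for one area (or pooled)."""
    area: str  # '' for pooled
    dimension: str
    counts: Mapping[str, int]
    percents: Mapping[str, float]


@dataclass(frozen=True)
class OverlapSummary:
    """Set sizes and intersections of per-region taxon sets."""
    regions: tuple[str, ...]
    sizes: Mapping[str, int]
    intersections: Mapping[tuple[str, ...], int]  # keyed by sorted region tuple
    union: int


def _tally(events: Iterable[UseEvent], dimension: str) -> Counter:
    """Dimension-appropriate deduplicated tally (see module docstring)."""
    fld = _FIELD[dimension]
    seen = set()
    counts: Counter = Counter()
    for e in events:
        tok = getattr(e, fld)
        if tok is None or tok == "":
            continue
        if dimension == "ailment":
            key = (e.voucher_id, e.ailment_code)
        else:
            key = (e.voucher_id, e.alternative_index, fld)
        if key in seen:
            continue
        seen.add(key)
        counts[tok] += 1
    return counts


def usage_frequency(events: Sequence[UseEvent], dimension: str, *,
                    per_area: bool = True,
                    unit: str = "events") -> list[FrequencyProfile]:
    """Frequency profile of one code dimension, per study area or pooled.

    ``unit='records'`` counts each record once per code regardless of
    alternatives (for the non-ailment dimensions this collapses repeats of
    the same token across alternatives).
    """
    if dimension not in _DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}; "
                         f"expected one of {_DIMENSIONS}")
    if unit not in ("events", "records"):
        raise ValueError(f"unknown unit {unit!r}")
    groups: dict[str, list[UseEvent]] = defaultdict(list)
    for e in events:
        groups[e.area if per_area else ""].append(e)
    profiles = []
    for area in sorted(groups):
        if unit == "records":
            fld = _FIELD[dimension]
            counts = Counter()
            for tok, _v in {( getattr(e, fld), e.voucher_id): None
                            for e in groups[area]
                            if getattr(e, fld) not in (None, "")}:
                counts[tok] += 1
        else:
            counts = _tally(groups[area], dimension)
        total = sum(counts.values())
        percents = {c: 100.0 * k / total for c, k in counts.items()} if total else {}
        profiles.append(FrequencyProfile(area, dimension, dict(counts), percents))
    return profiles


def top_conditions(events: Sequence[UseEvent], k: int,
                   area: str | None = None) -> list[tuple[str, int]]:
    """The ``k`` most treated ailment codes, descending by count with
    lexicographic tie-break."""
    if k < 1:
        raise ValueError("k must be >= 1")
    pool = [e for e in events if area is None or e.area == area]
    counts = _tally(pool, "ailment")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def genus_citation_counts(records: Iterable[SurveyRecord]) -> list[tuple[str, int]]:
    """Number of remedy reports per genus, unidentified taxa excluded;
    descending with lexicographic tie-break."""
    counts = Counter()
    for r in records:
        if r.taxon.rank == "unidentified":
            continue
        g = normalize_name(r.taxon.genus)
        counts[g[:1].upper() + g[1:]] += 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def shared_taxa(records: Iterable[SurveyRecord], *, level: str = "species",
                ) -> dict:
    """Taxa present in every study area and taxa present in exactly one.

    ``level='species'`` restricts to species-rank binomials (the resolution
    of the published four-way shared list); ``level='taxon'`` also carries
    genus-rank taxa, keyed as (genus, 'sp.').  Authority strings and
    infraspecific ranks never enter the identity.
    """
    if level not in ("species", "taxon"):
        raise ValueError(f"unknown level {level!r}")
    areas_by_taxon: dict[tuple, set] = defaultdict(set)
    for r in records:
        if r.taxon.rank == "unidentified":
            continue
        if level == "species" and r.taxon.rank != "species":
            continue
        areas_by_taxon[r.taxon.key()].add(r.area)
    all_areas = {a for areas in areas_by_taxon.values() for a in areas}
    if len(all_areas) < 2:
        raise ValueError("shared_taxa needs records from at least two areas")
    in_all = {t for t, a in areas_by_taxon.items() if a == all_areas}
    unique: dict[str, set] = {a: set() for a in sorted(all_areas)}
    for t, a in areas_by_taxon.items():
        if len(a) == 1:
            unique[next(iter(a))].add(t)
    return {"in_all_areas": in_all, "per_area_unique": unique}


def region_overlap(genus_sets: Mapping[str, set]) -> OverlapSummary:
    """Set-theoretic overlap of per-region genus sets (any number of
    regions; the published comparison uses three)."""
    regions = tuple(sorted(genus_sets))
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    sets = {r: {normalize_name(g) for g in genus_sets[r]} for r in regions}
    inter = {}
    for k in range(2, len(regions) + 1):
        for combo in combinations(regions, k):
            s = set.intersection(*(sets[r] for r in combo))
            inter[combo] = len(s)
    union = len(set.union(*sets.values()))
    summary = OverlapSummary(regions, {r: len(sets[r]) for r in regions},
                             inter, union)
    # inclusion-exclusion sanity (exact for sets)
    total = 0
    for k in range(1, len(regions) + 1):
        for combo in combinations(regions, k):
            size = (summary.sizes[combo[0]] if k == 1
                    else summary.intersections[combo])
            total += size if k % 2 == 1 else -size
    assert total == union, "inclusion-exclusion violated"
    return summary


def combined_genus_table(per_region_counts: Mapping[str, Mapping[str, int]],
                         min_total: int = 0) -> pd.DataFrame:
    """Citation counts of genera present in *all* regions, with row totals;
    rows below ``min_total`` are dropped. Region columns keep input order."""
    regions = list(per_region_counts)
    norm = {r: {normalize_name(g): c for g, c in per_region_counts[r].items()}
            for r in regions}
    common = set.intersection(*(set(norm[r]) for r in regions))
    rows = []
    for g in sorted(common):
        counts = [norm[r][g] for r in regions]
        total = sum(counts)
        if total >= min_total:
            rows.append([g[:1].upper() + g[1:], *counts, total])
    return pd.DataFrame(rows, columns=["genus", *regions, "total"])


def novelty_screen(records: Iterable[SurveyRecord],
                   reference_species: Iterable[str]) -> set[str]:
    """Species-rank binomials in the survey that are absent from a
    reference species list; genus-rank records are ignored."""
    ref = {normalize_name(s) for s in reference_species}
    out = set()
    for r in records:
        b = r.taxon.binomial()
        if b is not None and normalize_name(b) not in ref:
            out.add(b)
    return out
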