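"""Coded ethnobotanical survey records and regional flora checklists.

The survey data model mirrors the layout of the East Sepik traditional
medicine surveys: one row per remedy report, identified by a herbarium
voucher, with the taxon, family, local plant name and four controlled-
vocabulary code fields (ailment treated, plant part used, mode of
preparation, route of administration).  Multi-valued cells follow a small
grammar:

* ``/`` separates ailment codes (one report may treat several conditions);
* ``|`` separates remedy *alternatives* and is aligned positionally across
  the part/preparation/route columns;
* ``&`` joins items co-used within a single alternative.

Flora checklists are (family, genus, species) triples from a regional
plants database; deduplication and per-family counting provide the
reference denominators for the utilization analysis.
"""
from __future__ import annotations

import json
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TaxonName", "SurveyRecord", "UseEvent", "Vocabulary", "FloraChecklist",
    "ValidationIssue", "SchemaError", "EmptyInputError", "AlignmentError",
    "read_survey", "write_survey", "validate_codes", "explode_uses",
    "harmonize_family", "harmonize_records", "dedupe_checklist",
    "family_counts", "medicinal_family_counts",
    "load_vocabularies", "load_family_synonyms", "load_es_survey",
    "load_survey_changelog", "normalize_name",
]

STUDY_AREAS = ("DK", "BK", "GW", "MS")

#: canonical column names of the delimited survey schema
CANONICAL_COLUMNS = ("voucher", "family", "genus", "species", "authority",
                     "local_name", "ailments", "parts", "preps", "routes",
                     "area")


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


class EmptyInputError(ValueError):
    """An input table contains no data rows."""


class AlignmentError(ValueError):
    """'|'-separated code cells of a record have incompatible cardinalities."""


def normalize_name(name: str) -> str:
    """Case/diacritic/whitespace-insensitive canonical form of a taxon or
    family name component ('' for missing)."""
    s = unicodedata.normalize("NFKD", str(name or ""))
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    return re.sub(r"\s+", " ", s).strip().casefold()


def _cap(name: str) -> str:
    s = normalize_name(name)
    return s[:1].upper() + s[1:] if s else ""


@dataclass(frozen=True)
class TaxonName:
    """A survey taxon: full binomial, genus-level ('sp.') or unidentified."""
    genus: str
    specific_epithet: str | None = None
    authority: str | None = None
    rank: str = "species"  # species | genus | unidentified

    def __post_init__(self):
        if self.rank not in ("species", "genus", "unidentified"):
            raise ValueError(f"unknown rank {self.rank!r}")
        if self.rank == "species" and not self.specific_epithet:
            raise ValueError("rank=species requires a specific epithet")
        if self.rank == "genus" and self.specific_epithet not in (None, "", "sp."):
            raise ValueError("rank=genus must not carry an epithet")
        if self.rank != "unidentified" and not self.genus:
            raise ValueError("genus required unless unidentified")

    def key(self) -> tuple[str, str]:
        """Identity used for cross-report matching: case-insensitive,
        authority ignored, genus-level taxa keyed as (genus, 'sp.')."""
        if self.rank == "species":
            return (normalize_name(self.genus), normalize_name(self.specific_epithet))
        if self.rank == "genus":
            return (normalize_name(self.genus), "sp.")
        return ("", "")

    def binomial(self) -> str | None:
        if self.rank != "species":
            return None
        return f"{_cap(self.genus)} {normalize_name(self.specific_epithet)}"


@dataclass(frozen=True)
class SurveyRecord:
    """One remedy report (one row of the survey table)."""
    voucher_id: str
    taxon: TaxonName
    family: str
    local_name: str
    ailment_text: str
    ailment_codes: tuple[str, ...]
    part_codes: tuple[str, ...]   # one entry per '|'-alternative
    prep_codes: tuple[str, ...]
    route_codes: tuple[str, ...]
    area: str

    def __post_init__(self):
        if not self.ailment_codes:
            raise ValueError(f"{self.voucher_id}: ailment_codes must be non-empty")


@dataclass(frozen=True)
class UseEvent:
    """One (remedy alternative x ailment) use occurrence of a record."""
    voucher_id: str
    area: str
    family: str
    taxon: TaxonName
    ailment_code: str
    part_code: str | None
    prep_code: str | None
    route_code: str | None
    alternative_index: int


@dataclass(frozen=True)
class Vocabulary:
    """Controlled vocabulary for one code dimension."""
    dimension: str  # ailment | part | preparation | route
    codes: Mapping[str, str]

    def __post_init__(self):
        if not self.codes:
            raise ValueError("vocabulary must be non-empty")

    def __contains__(self, token: str) -> bool:
        return token in self.codes


@dataclass(frozen=True)
class ValidationIssue:
    voucher_id: str
    dimension: str
    token: str


@dataclass(frozen=True)
class FloraChecklist:
    """Deduplicated (family, genus, species) triples for one region."""
    region: str
    entries: frozenset[tuple[str, str, str]]

    def __len__(self):
        return len(self.entries)


# ---------------------------------------------------------------------------
# cell grammar

def split_ailments(cell: str) -> tuple[str, ...]:
    return tuple(t.strip() for t in str(cell).split("/") if t.strip())


def split_alternatives(cell: str) -> tuple[str, ...]:
    """Split a part/prep/route cell on '|'; '&'-joined co-used items stay a
    single token per alternative."""
    if cell is None or str(cell).strip() == "" or str(cell) == "nan":
        return ()
    out = []
    for alt in str(cell).split("|"):
        toks = [t.strip() for t in alt.split("&") if t.strip()]
        out.append(" & ".join(toks))
    return tuple(out)


def _join_alternatives(alts: Sequence[str]) -> str:
    return " | ".join(alts)


# ---------------------------------------------------------------------------
# i/o

_REQUIRED = {"voucher": "voucher", "family": "family", "ailments": "ailments",
             "parts": "parts", "preps": "preps", "routes": "routes",
             "area": "area"}


def read_survey(path, *, sep: str = "\t", columns: Mapping[str, str] | None = None,
                ) -> list[SurveyRecord]:
    """Read a delimited survey table into records.

    ``columns`` optionally maps canonical names to the file's header names.
    Raises :class:`SchemaError` for a missing mandatory column and
    :class:`EmptyInputError` for a table without data rows.
    """
    colmap = dict(columns or {})
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty survey file") from None
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")

    def col(name, default=""):
        src = colmap.get(name, name)
        if src in df.columns:
            return df[src].astype(str)
        if name in _REQUIRED:
            raise SchemaError(f"{path}: missing mandatory column {src!r}")
        return pd.Series([default] * len(df), index=df.index)

    records = []
    fields = {n: col(n) for n in CANONICAL_COLUMNS}
    fields["ailment_text"] = col("ailment_text")
    for i in df.index:
        genus = fields["genus"][i].strip()
        species = fields["species"][i].strip()
        authority = fields["authority"][i].strip() or None
        if not genus:
            taxon = TaxonName("", None, None, "unidentified")
        elif not species or species == "sp.":
            taxon = TaxonName(genus, None, authority, "genus")
        else:
            taxon = TaxonName(genus, species, authority, "species")
        records.append(SurveyRecord(
            voucher_id=fields["voucher"][i].strip(),
            taxon=taxon,
            family=fields["family"][i].strip(),
            local_name=fields["local_name"][i].strip(),
            ailment_text=fields["ailment_text"][i].strip(),
            ailment_codes=split_ailments(fields["ailments"][i]),
            part_codes=split_alternatives(fields["parts"][i]),
            prep_codes=split_alternatives(fields["preps"][i]),
            route_codes=split_alternatives(fields["routes"][i]),
            area=fields["area"][i].strip(),
        ))
    vouchers = [r.voucher_id for r in records]
    dupes = [v for v, c in Counter(vouchers).items() if c > 1]
    if dupes:
        raise SchemaError(f"{path}: duplicate voucher ids {dupes}")
    return records


def records_to_frame(records: Iterable[SurveyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "voucher": r.voucher_id,
            "family": r.family,
            "genus": r.taxon.genus,
            "species": r.taxon.specific_epithet or "",
            "authority": r.taxon.authority or "",
            "local_name": r.local_name,
            "ailment_text": r.ailment_text,
            "ailments": "/".join(r.ailment_codes),
            "parts": _join_alternatives(r.part_codes),
            "preps": _join_alternatives(r.prep_codes),
            "routes": _join_alternatives(r.route_codes),
            "area": r.area,
        })
    return pd.DataFrame(rows)


def write_survey(records: Iterable[SurveyRecord], path, *, sep: str = "\t") -> None:
    records_to_frame(records).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# validation

def validate_codes(records: Iterable[SurveyRecord],
                   vocabs: Mapping[str, Vocabulary]) -> list[ValidationIssue]:
    """Report every code token not in its controlled vocabulary.

    Unknown tokens are reported, never repaired or fatal; records are not
    mutated.  '&'-joined tokens are validated atom by atom.
    """
    issues = []
    for r in records:
        for code in r.ailment_codes:
            if code not in vocabs["ailment"]:
                issues.append(ValidationIssue(r.voucher_id, "ailment", code))
        for dim, cell in (("part", r.part_codes), ("preparation", r.prep_codes),
                          ("route", r.route_codes)):
            for alt in cell:
                for atom in alt.split(" & "):
                    if atom and atom not in vocabs[dim]:
                        issues.append(ValidationIssue(r.voucher_id, dim, atom))
    return issues


def issues_to_frame(issues: Iterable[ValidationIssue]) -> pd.DataFrame:
    return pd.DataFrame([vars(i) for i in issues],
                        columns=["voucher_id", "dimension", "token"])


# ---------------------------------------------------------------------------
# explosion into use events

def explode_uses(record: SurveyRecord) -> list[UseEvent]:
    """One event per (ailment code x remedy alternative).

    Length-1 (or empty) part/prep/route cells broadcast across alternatives;
    two cells with differing cardinalities both > 1 raise
    :class:`AlignmentError`.
    """
    cells = {"parts": record.part_codes, "preps": record.prep_codes,
             "routes": record.route_codes}
    lens = {k: len(v) for k, v in cells.items()}
    n_alt = max([1, *lens.values()])
    bad = {k: n for k, n in lens.items() if n not in (0, 1, n_alt)}
    if bad:
        raise AlignmentError(
            f"{record.voucher_id}: misaligned '|' cardinalities {lens}")

    def at(cell, i):
        if not cell:
            return None
        return cell[i] if len(cell) > 1 else cell[0]

    events = []
    for i in range(n_alt):
        for code in record.ailment_codes:
            events.append(UseEvent(
                voucher_id=record.voucher_id, area=record.area,
                family=record.family, taxon=record.taxon, ailment_code=code,
                part_code=at(record.part_codes, i),
                prep_code=at(record.prep_codes, i),
                route_code=at(record.route_codes, i),
                alternative_index=i))
    return events


# ---------------------------------------------------------------------------
# family harmonization and checklist handling

def harmonize_family(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Map historic family names to their canonical form; unknown names pass
    through unchanged apart from case/whitespace normalization. Idempotent."""
    canon = _cap(name)
    if synonyms:
        lowered = {normalize_name(k): _cap(v) for k, v in synonyms.items()}
        canon = lowered.get(normalize_name(canon), canon)
    return canon


def harmonize_records(records: Iterable[SurveyRecord],
                      synonyms: Mapping[str, str] | None = None,
                      ) -> list[SurveyRecord]:
    syn = load_family_synonyms() if synonyms is None else synonyms
    return [replace(r, family=harmonize_family(r.family, syn)) for r in records]


def dedupe_checklist(rows: Iterable[tuple[str, str, str]], *,
                     region: str = "") -> FloraChecklist:
    """Set semantics on normalized (family, genus, species) triples.

    A row with an empty family is rejected with its index.
    """
    entries = set()
    for i, (fam, gen, sp) in enumerate(rows):
        f = _cap(fam)
        if not f:
            raise ValueError(f"checklist row {i}: empty family")
        entries.add((f, _cap(gen), normalize_name(sp)))
    return FloraChecklist(region=region, entries=frozenset(entries))


def family_counts(checklist: FloraChecklist) -> dict[str, int]:
    """Number of checklist entries (taxa) per family."""
    return dict(Counter(fam for fam, _, _ in checklist.entries))


def medicinal_family_counts(records: Iterable[SurveyRecord], *,
                            unit: str = "distinct_taxa") -> dict[str, int]:
    """Per-family tally of the survey, either counting distinct taxa
    (the unit of the utilization tables) or raw report entries.

    Unidentified taxa are excluded from distinct-taxa counts unless a
    family is stated; every row counts under unit='entries'.
    """
    if unit == "entries":
        return dict(Counter(r.family for r in records))
    if unit != "distinct_taxa":
        raise ValueError(f"unknown unit {unit!r}")
    seen: dict[str, set] = {}
    for r in records:
        if r.taxon.rank == "unidentified" and normalize_name(r.family) in (
                "", "not identified"):
            continue
        key = r.taxon.key() if r.taxon.rank != "unidentified" else (
            "unidentified", r.voucher_id)
        seen.setdefault(r.family, set()).add(key)
    return {fam: len(taxa) for fam, taxa in seen.items()}


# ---------------------------------------------------------------------------
# packaged data

def _data(name: str):
    return resources.files("ethnoutil.data").joinpath(name)


def load_vocabularies() -> dict[str, Vocabulary]:
    raw = json.loads(_data("vocabularies.json").read_text())
    return {dim: Vocabulary(dim, codes) for dim, codes in raw.items()}


def load_family_synonyms() -> dict[str, str]:
    return json.loads(_data("family_synonyms.json").read_text())


def load_es_survey(*, harmonize: bool = False) -> list[SurveyRecord]:
    """The packaged East Sepik survey table (299 coded remedy reports from
    the four study areas DK, BK, GW and MS)."""
    with resources.as_file(_data("es_survey.tsv")) as p:
        records = read_survey(p)
    return harmonize_records(records) if harmonize else records


def load_survey_changelog() -> str:
    """Curation log for the packaged survey table (flagged cells)."""
    return _data("es_survey.CHANGELOG").read_text()


def load_regional_family_counts() -> pd.DataFrame:
    """Printed per-family reference/survey counts for the three provinces
    against the two reference databases, with the published interval bounds
    and margins for cross-checking."""
    with resources.as_file(_data("regional_family_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"margin_printed": str},
                           keep_default_na=False)


def load_common_genera_counts() -> pd.DataFrame:
    """Published per-province citation counts of the genera shared by all
    three provinces."""
    with resources.as_file(_data("common_genera_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_lesser_known_species() -> list[str]:
    """Species from the East Sepik survey reported as absent from the
    historical medicinal-plant literature for PNG."""
    return [l.strip() for l in
            _data("lesser_known_species.txt").read_text().splitlines()
            if l.strip() and not l.startswith("#")]
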