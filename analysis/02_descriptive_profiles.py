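#!/usr/bin/env python
"""Descriptive usage patterns of the East Sepik survey: what is treated,
with which plant parts, preparations and routes; which taxa are shared
between the four study areas; which species are absent from the historical
PNG medicinal-plant literature.

Findings: skin conditions dominate (73 instances), then respiratory (60),
fever (39), gastrointestinal (36) and malaria (29); Ficus is the most
cited genus (11 reports); four species occur in all four areas; 21
surveyed species are absent from the reference literature list.
"""
from pathlib import Path

import pandas as pd

import ethnoutil as eu

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

records = eu.load_es_survey(harmonize=True)
events = [e for r in records for e in eu.explode_uses(r)]

for dim in ("ailment", "part", "preparation", "route"):
    rows = []
    for prof in (eu.usage_frequency(events, dim, per_area=True)
                 + eu.usage_frequency(events, dim, per_area=False)):
        for code in sorted(prof.counts):
            rows.append({"area": prof.area or "ALL", "code": code,
                         "count": prof.counts[code],
                         "percent": round(prof.percents[code], 4)})
    pd.DataFrame(rows).to_csv(OUT / f"02_frequency_{dim}.tsv", sep="\t",
                              index=False)

top5 = eu.top_conditions(events, 5)
pd.DataFrame(top5, columns=["code", "count"]).to_csv(
    OUT / "02_top_conditions.tsv", sep="\t", index=False)
print("top five conditions (pooled):", top5)
for area in sorted({r.area for r in records}):
    print(f"  {area}:", eu.top_conditions(events, 5, area=area))

genus_counts = eu.genus_citation_counts(records)
pd.DataFrame(genus_counts, columns=["genus", "records"]).to_csv(
    OUT / "02_genus_counts.tsv", sep="\t", index=False)
print("most cited genera:", genus_counts[:6])

shared = eu.shared_taxa(records, level="species")
print("species in every area:",
      sorted(f"{g.capitalize()} {s}" for g, s in shared["in_all_areas"]))
taxon_level = eu.shared_taxa(records, level="taxon")
n_unique = sum(len(v) for v in taxon_level["per_area_unique"].values())
print(f"taxa unique to a single area: {n_unique}")
rows = [{"group": "in_all_areas", "taxon": f"{g.capitalize()} {s}"}
        for g, s in sorted(shared["in_all_areas"])]
for area, taxa in taxon_level["per_area_unique"].items():
    rows += [{"group": f"unique_{area}",
              "taxon": f"{g.capitalize()} {s}"} for g, s in sorted(taxa)]
pd.DataFrame(rows).to_csv(OUT / "02_shared_taxa.tsv", sep="\t", index=False)

# novelty screen against a synthetic reference list: all surveyed binomials
# minus the species the survey itself reported as previously undescribed
lesser = eu.load_lesser_known_species()
surveyed = {r.taxon.binomial() for r in records if r.taxon.binomial()}
novel = sorted(eu.novelty_screen(records, surveyed - set(lesser)))
pd.DataFrame({"species": novel}).to_csv(OUT / "02_novel_species.tsv",
                                        sep="\t", index=False)
print(f"species absent from the reference list: {len(novel)}")
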