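import pytest
from hypothesis import settings

import ethnoutil as eu

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def es_records():
    """The packaged East Sepik survey, families harmonized."""
    return eu.harmonize_records(eu.load_es_survey())


@pytest.fixture(scope="session")
def es_events(es_records):
    return [e for r in es_records for e in eu.explode_uses(r)]


@pytest.fixture(scope="session")
def vocabs():
    return eu.load_vocabularies()


@pytest.fixture(scope="session")
def regional_counts():
    return eu.load_regional_family_counts()


def region_tables(df):
    """Split the printed per-region count table into (total, family rows)
    per (reference, region) panel."""
    for (ref, region), g in df.groupby(["reference", "region"]):
        tot = g[g.group == "total"].iloc[0]
        total = eu.FamilyCount("Total", int(tot.n_reference), int(tot.x_used))
        fams = g[g.group != "total"]
        yield (ref, region), total, tot, fams
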