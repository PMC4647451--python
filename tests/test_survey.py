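"""Survey data model: parsing, cell grammar, validation, checklists."""
from collections import Counter

import pytest
from hypothesis import given, strategies as st

import ethnoutil as eu
from ethnoutil.survey import (AlignmentError, EmptyInputError, SchemaError,
                              issues_to_frame, records_to_frame,
                              split_alternatives)

HEADER = "voucher\tfamily\tgenus\tspecies\tauthority\tlocal_name\tailment_text\tailments\tparts\tpreps\troutes\tarea\n"


def make_survey(tmp_path, rows, header=HEADER):
    p = tmp_path / "survey.tsv"
    p.write_text(header + "".join(rows))
    return p


def row(voucher="X 01/01", family="Testaceae", genus="Genus", species="alba",
        ailments="FEV", parts="L", preps="D", routes="O", area="DK"):
    return (f"{voucher}\t{family}\t{genus}\t{species}\t\tlocal\ttext\t"
            f"{ailments}\t{parts}\t{preps}\t{routes}\t{area}\n")


class TestReadSurvey:
    def test_fixture_has_299_entries(self, es_records):
        assert len(es_records) == 299
        assert len({r.voucher_id for r in es_records}) == 299

    def test_fixture_unidentified_entries(self, es_records):
        unid = [r for r in es_records if r.taxon.rank == "unidentified"]
        assert len(unid) == 6

    def test_multivalued_ailment_cell_is_split(self, tmp_path):
        p = make_survey(tmp_path, [row(ailments="FEV/MAL")])
        (rec,) = eu.read_survey(p)
        assert rec.ailment_codes == ("FEV", "MAL")

    def test_single_codes_give_singleton_lists(self, tmp_path):
        p = make_survey(tmp_path, [row()])
        (rec,) = eu.read_survey(p)
        assert rec.ailment_codes == ("FEV",)
        assert rec.part_codes == ("L",)
        assert rec.prep_codes == ("D",)
        assert rec.route_codes == ("O",)

    def test_missing_mandatory_column_names_it(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("voucher\tfamily\n" + "X\tF\n")
        with pytest.raises(SchemaError, match="ailments"):
            eu.read_survey(p)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(EmptyInputError):
            eu.read_survey(p)
        p.write_text(HEADER)
        with pytest.raises(EmptyInputError):
            eu.read_survey(p)

    def test_duplicate_vouchers_rejected(self, tmp_path):
        p = make_survey(tmp_path, [row(), row()])
        with pytest.raises(SchemaError, match="duplicate"):
            eu.read_survey(p)

    def test_roundtrip_write_read(self, es_records, tmp_path):
        p = tmp_path / "roundtrip.tsv"
        eu.write_survey(es_records, p)
        again = eu.read_survey(p)
        assert again == es_records


class TestCellGrammar:
    @pytest.mark.parametrize("cell, expected", [
        ("L", ("L",)),
        ("L | Sap | Sap", ("L", "Sap", "Sap")),
        ("Stem & Root", ("Stem & Root",)),
        ("Sap & L | Seed", ("Sap & L", "Seed")),
        ("", ()),
    ])
    def test_alternative_splitting(self, cell, expected):
        assert split_alternatives(cell) == expected


class TestExplodeUses:
    def test_single_alternative_single_ailment(self, tmp_path):
        p = make_survey(tmp_path, [row(ailments="SKIN", parts="L", preps="S",
                                       routes="T")])
        (rec,) = eu.read_survey(p)
        (ev,) = eu.explode_uses(rec)
        assert (ev.ailment_code, ev.part_code, ev.prep_code, ev.route_code,
                ev.alternative_index) == ("SKIN", "L", "S", "T", 0)

    def test_two_ailments_one_alternative(self, tmp_path):
        # hand enumeration: FEV and MAL each get the same remedy
        p = make_survey(tmp_path, [row(ailments="FEV/MAL")])
        (rec,) = eu.read_survey(p)
        events = eu.explode_uses(rec)
        assert [(e.ailment_code, e.part_code) for e in events] == \
            [("FEV", "L"), ("MAL", "L")]

    def test_multi_alternative_cross_product(self, es_records):
        # the 4-ailment, 3-alternative record: 12 events by brute-force
        # enumeration, ailments distributed across aligned alternatives
        rec = next(r for r in es_records if r.voucher_id == "BK 022/06")
        assert rec.ailment_codes == ("MAL", "GAST", "RESP", "SKIN")
        assert rec.part_codes == ("L", "Sap", "Sap")
        events = eu.explode_uses(rec)
        expected = [(a, p) for p in ["L", "Sap", "Sap"]
                    for a in ["MAL", "GAST", "RESP", "SKIN"]]
        assert [(e.ailment_code, e.part_code) for e in events] == expected
        assert [e.alternative_index for e in events] == [0]*4 + [1]*4 + [2]*4

    def test_broadcast_of_singleton_cells(self, tmp_path):
        p = make_survey(tmp_path, [row(parts="Root", preps="M | C", routes="O")])
        (rec,) = eu.read_survey(p)
        events = eu.explode_uses(rec)
        assert [(e.part_code, e.prep_code, e.route_code) for e in events] == \
            [("Root", "M", "O"), ("Root", "C", "O")]

    def test_misaligned_cardinalities_raise_with_voucher(self, tmp_path):
        p = make_survey(tmp_path, [row(voucher="X 99/99", parts="L | B",
                                       preps="D | S | M")])
        (rec,) = eu.read_survey(p)
        with pytest.raises(AlignmentError, match="X 99/99"):
            eu.explode_uses(rec)

    def test_explosion_is_lossless_on_fixture(self, es_records):
        for rec in es_records:
            events = eu.explode_uses(rec)
            n_alt = max([1, *map(len, (rec.part_codes, rec.prep_codes,
                                       rec.route_codes))])
            assert Counter(e.ailment_code for e in events) == \
                Counter({c: n_alt for c in rec.ailment_codes})


class TestHarmonizeFamily:
    @pytest.mark.parametrize("name, expected", [
        ("Labiatae", "Lamiaceae"),
        ("Labiate", "Lamiaceae"),
        ("Gramineae", "Poaceae"),
        ("Lamiaceae", "Lamiaceae"),
        (" fabaceae ", "Fabaceae"),
    ])
    def test_known_mappings(self, name, expected):
        assert eu.harmonize_family(name, eu.load_family_synonyms()) == expected

    @given(st.text(alphabet=st.characters(whitelist_categories=("Lu", "Ll")),
                   min_size=1, max_size=20))
    def test_idempotent(self, name):
        syn = eu.load_family_synonyms()
        once = eu.harmonize_family(name, syn)
        assert eu.harmonize_family(once, syn) == once


class TestChecklist:
    def test_exact_duplicate_removed(self):
        cl = eu.dedupe_checklist([("F", "G", "s"), ("F", "G", "s")])
        assert len(cl) == 1

    def test_distinct_species_retained(self):
        cl = eu.dedupe_checklist([("F", "G", "s1"), ("F", "G", "s2")])
        assert len(cl) == 2

    def test_case_and_whitespace_insensitive(self):
        cl = eu.dedupe_checklist([("Fam", "Gen", "spec"),
                                  (" fam", "GEN ", "Spec")])
        assert len(cl) == 1

    def test_planted_duplicates(self):
        rows = [(f"Fam{i % 30:02d}", f"G{i:04d}", f"sp{i:04d}")
                for i in range(900)]
        rows += rows[:100]  # 100 planted duplicates
        cl = eu.dedupe_checklist(rows)
        assert len(cl) == 900

    def test_empty_family_rejected_with_index(self):
        with pytest.raises(ValueError, match="row 1"):
            eu.dedupe_checklist([("F", "G", "a"), ("", "G", "b")])

    def test_family_counts_examples(self):
        cl = eu.dedupe_checklist([("F1", "G1", "a"), ("F1", "G2", "b"),
                                  ("F2", "G3", "c")])
        assert eu.family_counts(cl) == {"F1": 2, "F2": 1}
        assert sum(eu.family_counts(cl).values()) == len(cl)

    def test_family_counts_permutation_and_duplication_invariant(self):
        rows = [("F1", "G1", "a"), ("F2", "G2", "b"), ("F1", "G3", "c")]
        base = eu.family_counts(eu.dedupe_checklist(rows))
        shuffled = eu.family_counts(eu.dedupe_checklist(rows[::-1] + rows))
        assert base == shuffled


class TestMedicinalFamilyCounts:
    def test_units_on_toy_records(self, tmp_path):
        rows = [row(voucher="A 1/1", area="DK"),
                row(voucher="A 2/1", area="MS")]
        recs = eu.read_survey(make_survey(tmp_path, rows))
        assert eu.medicinal_family_counts(recs, unit="distinct_taxa") == \
            {"Testaceae": 1}
        assert eu.medicinal_family_counts(recs, unit="entries") == \
            {"Testaceae": 2}

    def test_fixture_entries_total(self, es_records):
        counts = eu.medicinal_family_counts(es_records, unit="entries")
        assert sum(counts.values()) == 299

    def test_unknown_unit(self, es_records):
        with pytest.raises(ValueError, match="unit"):
            eu.medicinal_family_counts(es_records, unit="bogus")


class TestValidateCodes:
    def test_listed_code_passes(self, tmp_path, vocabs):
        recs = eu.read_survey(make_survey(tmp_path, [row(routes="O")]))
        assert eu.validate_codes(recs, vocabs) == []

    def test_unknown_token_reported_not_fatal(self, tmp_path, vocabs):
        recs = eu.read_survey(make_survey(tmp_path, [row(routes="Q")]))
        issues = eu.validate_codes(recs, vocabs)
        assert [(i.dimension, i.token) for i in issues] == [("route", "Q")]
        assert recs[0].route_codes == ("Q",)  # record untouched

    def test_fixture_report_lists_curation_oddities(self, es_records, vocabs):
        issues = eu.validate_codes(es_records, vocabs)
        assert {(i.dimension, i.token) for i in issues} == {
            ("preparation", "S?"), ("preparation", "-"),
            ("preparation", "R or H"), ("part", "L or B")}
        df = issues_to_frame(issues)
        assert list(df.columns) == ["voucher_id", "dimension", "token"]
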