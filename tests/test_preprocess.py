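"""Cleaning rules: professional filter, dedup, age units, case assembly."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerskit.io import RawDemoRecord, RawDrugRecord, RawReacRecord
from faerskit.preprocess import (
    CleanCaseTable,
    build_case_table,
    deduplicate_cases,
    extract_primary_suspect,
    filter_professional,
    normalize_age,
    normalize_ingredient,
    preprocess_quarters,
)


def demo(pid, cid, version=1, age=30.0, cod="YR", sex="F", occp="MD"):
    return RawDemoRecord(primaryid=str(pid), caseid=str(cid), caseversion=version,
                         age=age, age_cod=cod, sex=sex, occp_cod=occp)


class TestProfessionalFilter:
    @pytest.mark.parametrize(
        "occp, kept",
        [("MD", True), ("PH", True), ("OT", True), ("HP", True), ("hp", True),
         ("CN", False), ("", False), (None, False), ("LW", False)],
    )
    def test_occupation_codes(self, occp, kept):
        records = [demo(1, 1, occp=occp)]
        assert (len(filter_professional(records)) == 1) is kept

    def test_empty_input(self):
        assert filter_professional([]) == []

    def test_count_matches_exhaustive_count(self):
        rng = random.Random(42)
        occs = [rng.choice(["MD", "PH", "OT", "HP", "CN"]) for _ in range(1000)]
        records = [demo(i, i, occp=o) for i, o in enumerate(occs)]
        expected = sum(1 for o in occs if o != "CN")
        assert len(filter_professional(records)) == expected


class TestDeduplicate:
    def test_latest_version_survives(self):
        records = [demo(1001, 100, version=1), demo(1002, 100, version=2)]
        assert [r.primaryid for r in deduplicate_cases(records)] == ["1002"]

    def test_single_record_is_itself(self):
        records = [demo(1001, 100)]
        assert deduplicate_cases(records) == records

    def test_version_tie_broken_by_padded_primaryid(self):
        # "99" < "100" as zero-padded strings would be "099" < "100"
        records = [demo("99", 7, version=3), demo("100", 7, version=3)]
        assert deduplicate_cases(records)[0].primaryid == "100"

    def test_missing_version_superseded_by_any_explicit_version(self):
        records = [demo(2, 5, version=None), demo(1, 5, version=1)]
        assert deduplicate_cases(records)[0].primaryid == "1"

    def test_random_versions_against_brute_force(self):
        rng = random.Random(7)
        records = []
        pid = 0
        for cid in range(50):
            for _ in range(rng.randint(1, 4)):
                pid += 1
                records.append(demo(pid, cid, version=rng.randint(1, 9)))
        rng.shuffle(records)
        result = {r.caseid: r for r in deduplicate_cases(records)}
        assert len(result) == 50
        pad = max(len(r.primaryid) for r in records)
        for cid in {r.caseid for r in records}:
            group = [r for r in records if r.caseid == cid]
            best = max(group, key=lambda r: (r.caseversion, r.primaryid.rjust(pad, "0")))
            assert result[cid] == best


class TestNormalizeAge:
    @pytest.mark.parametrize(
        "age, cod, years",
        [
            (30, "YR", 30.0),
            (30, None, 30.0),
            (24, "MON", 2.0),
            (1, "DEC", 10.0),
            (52.1775, "WK", 1.0),
            (365.25, "DY", 1.0),
            (8766, "HR", 1.0),
            (150, "YR", None),       # beyond plausible lifespan
            (13, "DEC", None),       # 130 years
            (30, "FORTNIGHT", None), # unrecognized unit
            (-1, "YR", None),
            (None, "YR", None),
        ],
    )
    def test_unit_conversion(self, age, cod, years):
        assert normalize_age(age, cod) == years

    def test_rounding_to_four_decimals(self):
        assert normalize_age(100, "DY") == round(100 / 365.25, 4)


class TestPrimarySuspect:
    def test_normalization(self):
        records = [RawDrugRecord("1", 1, "PS", "  hydroxychloroquine   sulfate ")]
        assert extract_primary_suspect(records) == {"1": frozenset({"HYDROXYCHLOROQUINE SULFATE"})}

    def test_non_ps_roles_ignored(self):
        records = [RawDrugRecord("1", 1, "SS", "ASPIRIN"),
                   RawDrugRecord("1", 2, "C", "IBUPROFEN")]
        assert extract_primary_suspect(records) == {}

    def test_two_ps_ingredients(self):
        records = [RawDrugRecord("1", 1, "PS", "A"), RawDrugRecord("1", 2, "PS", "B")]
        assert extract_primary_suspect(records)["1"] == frozenset({"A", "B"})

    def test_combination_product_kept_as_single_token(self):
        records = [RawDrugRecord("1", 1, "PS", "NIRMATRELVIR\\RITONAVIR")]
        assert extract_primary_suspect(records)["1"] == frozenset({"NIRMATRELVIR/RITONAVIR"})

    def test_empty_prod_ai_dropped(self):
        records = [RawDrugRecord("1", 1, "PS", "   ")]
        assert extract_primary_suspect(records) == {}


def test_normalize_ingredient_backslash_and_case():
    assert normalize_ingredient(" nirmatrelvir\\Ritonavir  ") == "NIRMATRELVIR/RITONAVIR"


class TestBuildCaseTable:
    def trio(self):
        demo_recs = [demo(11, 1)]
        drug_recs = [RawDrugRecord("11", 1, "PS", "DRUG_A")]
        reac_recs = [RawReacRecord("11", "Nausea")]
        return demo_recs, drug_recs, reac_recs

    def test_single_complete_case(self):
        table = build_case_table(*self.trio())
        assert len(table) == 1
        case = table[0]
        assert case.sex == "female" and case.age_years == 30.0
        assert case.ps_ingredients == {"DRUG_A"} and case.pts == {"Nausea"}

    def test_case_without_reactions_excluded(self):
        d, g, _ = self.trio()
        table = build_case_table(d, g, [])
        assert len(table) == 0
        assert table.provenance.dropped_missing_essentials == 1

    def test_case_without_ps_drug_excluded(self):
        d, _, r = self.trio()
        table = build_case_table(d, [], r)
        assert len(table) == 0
        assert table.provenance.dropped_missing_essentials == 1

    def test_multi_ps_excluded_by_default_kept_when_disabled(self):
        d, g, r = self.trio()
        g = g + [RawDrugRecord("11", 2, "PS", "DRUG_B")]
        assert len(build_case_table(d, g, r)) == 0
        assert build_case_table(d, g, r).provenance.dropped_multi_ps == 1
        table = build_case_table(d, g, r, single_ps_only=False)
        assert table[0].ps_ingredients == {"DRUG_A", "DRUG_B"}

    def test_sex_mapping(self):
        d = [demo(11, 1, sex="M"), demo(12, 2, sex="UNK"), demo(13, 3, sex=None)]
        g = [RawDrugRecord(str(p), 1, "PS", "A") for p in (11, 12, 13)]
        r = [RawReacRecord(str(p), "Rash") for p in (11, 12, 13)]
        table = build_case_table(d, g, r)
        assert [c.sex for c in table] == ["male", "unknown", "unknown"]

    def test_six_case_fixture_by_hand(self, six_case_table):
        d, g, r = [], [], []
        for case in six_case_table:
            pid = case.primaryid
            d.append(RawDemoRecord(primaryid=pid, caseid=case.caseid, caseversion=1,
                                   age=case.age_years, age_cod="YR",
                                   sex={"female": "F", "male": "M"}.get(case.sex),
                                   occp_cod=case.reporter))
            for ing in case.ps_ingredients:
                g.append(RawDrugRecord(pid, 1, "PS", ing))
            for pt in case.pts:
                r.append(RawReacRecord(pid, pt))
        table = build_case_table(d, g, r)
        assert sorted(table, key=lambda c: c.caseid) == sorted(six_case_table, key=lambda c: c.caseid)


class TestFullPipeline:
    def raw(self):
        d = [
            demo(11, 1, occp="MD"),
            demo(21, 2, version=1, occp="PH"), demo(22, 2, version=2, occp="PH"),
            demo(31, 3, occp="CN"),
            demo(41, 4, occp="MD"),  # no reactions -> missing essentials
        ]
        g = [RawDrugRecord(p, 1, "PS", "DRUG_A") for p in ("11", "21", "22", "31", "41")]
        r = [RawReacRecord(p, "Nausea") for p in ("11", "21", "22", "31")]
        return d, g, r

    def test_provenance_conservation(self):
        table = preprocess_quarters(*self.raw())
        p = table.provenance
        assert p.raw_demo_rows == 5
        assert p.dropped_nonprofessional == 1
        assert p.dropped_duplicate_version == 1
        assert p.dropped_missing_essentials == 1
        assert p.retained == 2
        assert p.conserved()

    def test_order_invariance(self):
        d, g, r = self.raw()
        table1 = preprocess_quarters(d, g, r)
        rng = random.Random(3)
        for seq in (d, g, r):
            rng.shuffle(seq)
        table2 = preprocess_quarters(d, g, r)
        assert sorted(table1, key=lambda c: c.caseid) == sorted(table2, key=lambda c: c.caseid)

    def test_idempotence_on_already_clean_data(self):
        table1 = preprocess_quarters(*self.raw())
        # rebuild raw records from the clean cases and run the pipeline again
        d = [RawDemoRecord(c.primaryid, c.caseid, 1, c.age_years, "YR",
                           {"female": "F", "male": "M"}.get(c.sex), c.reporter)
             for c in table1]
        g = [RawDrugRecord(c.primaryid, 1, "PS", i) for c in table1 for i in c.ps_ingredients]
        r = [RawReacRecord(c.primaryid, pt) for c in table1 for pt in c.pts]
        table2 = preprocess_quarters(d, g, r)
        assert sorted(table2, key=lambda c: c.caseid) == sorted(table1, key=lambda c: c.caseid)
        assert table2.provenance.retained == len(table1)
        assert table2.provenance.dropped_nonprofessional == 0


def test_clean_table_tsv_round_trip(tmp_path, six_case_table):
    path = six_case_table.to_tsv(tmp_path / "cases.tsv")
    loaded = CleanCaseTable.from_tsv(path)
    assert sorted(loaded, key=lambda c: c.caseid) == sorted(six_case_table, key=lambda c: c.caseid)


def test_duplicate_caseid_rejected(six_case_table):
    with pytest.raises(ValueError, match="duplicate caseid"):
        CleanCaseTable(list(six_case_table) + [six_case_table[0]])


@settings(max_examples=30, derandomize=True)
@given(st.data())
def test_conservation_property(data):
    """Every raw demo row lands in exactly one provenance bucket."""
    n = data.draw(st.integers(0, 40))
    d, g, r = [], [], []
    for i in range(n):
        occp = data.draw(st.sampled_from(["MD", "PH", "CN", None]))
        versions = data.draw(st.integers(1, 3))
        for v in range(1, versions + 1):
            pid = f"{i}{v}"
            d.append(RawDemoRecord(pid, str(i), v, 40.0, "YR", "F", occp))
            if data.draw(st.booleans()):
                g.append(RawDrugRecord(pid, 1, "PS", "A"))
            if data.draw(st.booleans()):
                r.append(RawReacRecord(pid, "Nausea"))
    table = preprocess_quarters(d, g, r)
    assert table.provenance.conserved()
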