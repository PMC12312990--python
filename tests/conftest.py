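import pytest

from faerskit.preprocess import CleanCase, CleanCaseTable


def make_case(caseid, ingredients, pts, sex="female", age=60.0, reporter="MD"):
    return CleanCase(
        caseid=str(caseid),
        primaryid=f"{caseid}1",
        sex=sex,
        age_years=age,
        reporter=reporter,
        ps_ingredients=frozenset(ingredients),
        pts=frozenset(pts),
    )


@pytest.fixture
def six_case_table():
    """Six hand-enumerable cases: three on DRUG_A, three on DRUG_B.

    For drug group {DRUG_A} and reaction PT_X the contingency table is
    (a, b, c, d) = (2, 1, 1, 2); for PT_Y it is (2, 1, 2, 1).
    """
    cases = [
        make_case(1, {"DRUG_A"}, {"PT_X"}, sex="female", age=62.0),
        make_case(2, {"DRUG_A"}, {"PT_Y"}, sex="male", age=41.0),
        make_case(3, {"DRUG_A"}, {"PT_X", "PT_Y"}, sex="female", age=73.0),
        make_case(4, {"DRUG_B"}, {"PT_X"}, sex="male", age=55.0),
        make_case(5, {"DRUG_B"}, {"PT_Y"}, sex="female", age=30.0),
        make_case(6, {"DRUG_B"}, {"PT_Y"}, sex="unknown", age=None),
    ]
    return CleanCaseTable(cases)
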