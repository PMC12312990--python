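"""Cleaning FAERS raw records into one analysis-ready case table.

The cleaning pipeline mirrors standard pharmacovigilance practice for
spontaneous-report data:

1. keep only reports filed by health-care professionals (occupation codes
   HP, MD, OT, PH);
2. deduplicate resubmitted reports, keeping only the latest version of
   each case (maximal ``caseversion``; ties broken by maximal zero-padded
   ``primaryid``);
3. extract the active ingredients reported as the *primary suspect* (role
   code PS) drug of each report;
4. drop reports missing essential information — no suspect ingredient or
   no reaction term;
5. optionally drop reports implicating more than one primary-suspect
   ingredient (``single_ps_only``, on by default, restricting the cohort
   to single-drug reports).

The counting unit downstream is the *case*: after deduplication a case
contributes at most once to any contingency cell, however many drug or
reaction rows it carried.  Every raw demo row lands in exactly one
provenance bucket, so exclusions are fully auditable.
"""

from __future__ import annotations

import json
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Union

import pandas as pd

from .io import PROFESSIONAL_OCCUPATIONS, RawDemoRecord, RawDrugRecord, RawReacRecord

# hours per Julian year (365.25 d); weeks per Julian year = 365.25/7
_AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

MAX_PLAUSIBLE_AGE = 120.0

_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class CleanCase:
    """One deduplicated, professional-reported, analysis-ready case."""

    caseid: str
    primaryid: str
    sex: str  # female | male | unknown
    age_years: Optional[float]
    reporter: Optional[str]  # occupation code, kept for audit
    ps_ingredients: FrozenSet[str]
    pts: FrozenSet[str]


@dataclass
class Provenance:
    """Per-stage exclusion accounting for one preprocessing run."""

    quarters: tuple = ()
    raw_demo_rows: int = 0
    dropped_nonprofessional: int = 0
    dropped_duplicate_version: int = 0
    dropped_missing_essentials: int = 0
    dropped_multi_ps: int = 0
    retained: int = 0
    # informational, not part of the demo-row conservation identity
    dropped_empty_prod_ai_rows: int = 0
    invalid_age_records: int = 0

    def conserved(self) -> bool:
        """Every raw demo row is in exactly one bucket."""
        return self.raw_demo_rows == (
            self.retained
            + self.dropped_nonprofessional
            + self.dropped_duplicate_version
            + self.dropped_missing_essentials
            + self.dropped_multi_ps
        )

    def to_dict(self) -> dict:
        return dict(self.__dict__, quarters=list(self.quarters))


class CleanCaseTable(Sequence):
    """A sequence of :class:`CleanCase` with provenance; caseids unique."""

    def __init__(self, cases: Iterable[CleanCase], provenance: Optional[Provenance] = None):
        self.cases: List[CleanCase] = list(cases)
        seen = set()
        for c in self.cases:
            if c.caseid in seen:
                raise ValueError(f"duplicate caseid {c.caseid!r} in CleanCaseTable")
            seen.add(c.caseid)
        self.provenance = provenance if provenance is not None else Provenance(retained=len(self.cases))

    def __len__(self) -> int:
        return len(self.cases)

    def __getitem__(self, i):
        return self.cases[i]

    def __iter__(self) -> Iterator[CleanCase]:
        return iter(self.cases)

    # -- vocabulary helpers (used by the CLI for near-match suggestions) --

    def ingredient_vocabulary(self) -> List[str]:
        vocab = set()
        for c in self.cases:
            vocab.update(c.ps_ingredients)
        return sorted(vocab)

    def pt_vocabulary(self) -> List[str]:
        vocab = set()
        for c in self.cases:
            vocab.update(c.pts)
        return sorted(vocab)

    # -- serialization: tab-separated, sets as "|"-joined sorted lists --

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "caseid": [c.caseid for c in self.cases],
                "primaryid": [c.primaryid for c in self.cases],
                "sex": [c.sex for c in self.cases],
                "age_years": [c.age_years for c in self.cases],
                "reporter": [c.reporter or "" for c in self.cases],
                "ps_ingredients": ["|".join(sorted(c.ps_ingredients)) for c in self.cases],
                "pts": ["|".join(sorted(c.pts)) for c in self.cases],
            }
        )

    def to_tsv(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path

    def write_provenance(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.provenance.to_dict(), indent=2) + "\n")
        return path

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "CleanCaseTable":
        df = pd.read_csv(path, sep="\t", dtype={"caseid": str, "primaryid": str}, keep_default_na=False)
        cases = []
        for row in df.itertuples(index=False):
            age = row.age_years
            if age == "" or (isinstance(age, float) and pd.isna(age)):
                age = None
            else:
                age = float(age)
            cases.append(
                CleanCase(
                    caseid=str(row.caseid),
                    primaryid=str(row.primaryid),
                    sex=row.sex,
                    age_years=age,
                    reporter=row.reporter or None,
                    ps_ingredients=frozenset(s for s in str(row.ps_ingredients).split("|") if s),
                    pts=frozenset(s for s in str(row.pts).split("|") if s),
                )
            )
        prov = Provenance(retained=len(cases))
        return cls(cases, prov)


def filter_professional(records: Sequence[RawDemoRecord]) -> List[RawDemoRecord]:
    """Keep only records reported by health-care professionals.

    Retains exactly the records whose ``occp_cod`` is HP, MD, OT or PH
    (case-insensitive); consumers (CN), empty and unrecognized codes are
    dropped.
    """
    return [
        r
        for r in records
        if r.occp_cod is not None and r.occp_cod.strip().upper() in PROFESSIONAL_OCCUPATIONS
    ]


def _dedup_key(record: RawDemoRecord, pad: int):
    version = record.caseversion if record.caseversion is not None else 0
    return (version, record.primaryid.rjust(pad, "0"))


def deduplicate_cases(records: Sequence[RawDemoRecord]) -> List[RawDemoRecord]:
    """Keep, per caseid, only the latest report version.

    The surviving record has maximal ``caseversion`` (absent treated as
    0); ties are broken by maximal ``primaryid`` compared as strings after
    left-zero-padding to equal length.  Output order follows first
    appearance of each caseid.
    """
    if not records:
        return []
    pad = max(len(r.primaryid) for r in records)
    best: Dict[str, RawDemoRecord] = {}
    order: List[str] = []
    for r in records:
        cur = best.get(r.caseid)
        if cur is None:
            best[r.caseid] = r
            order.append(r.caseid)
        elif _dedup_key(r, pad) > _dedup_key(cur, pad):
            best[r.caseid] = r
    return [best[cid] for cid in order]


def normalize_age(age: Optional[float], age_cod: Optional[str]) -> Optional[float]:
    """Convert a FAERS (age, unit-code) pair to years.

    DEC is decades, YR years (also assumed when the code is absent), MON
    months, WK weeks, DY days, HR hours.  The result is rounded to 4
    decimals; negative ages, unrecognized codes and ages above 120 years
    yield ``None``.
    """
    if age is None or age < 0:
        return None
    code = (age_cod or "YR").strip().upper() or "YR"
    factor = _AGE_FACTORS.get(code)
    if factor is None:
        return None
    years = round(age * factor, 4)
    if years > MAX_PLAUSIBLE_AGE:
        return None
    return years


def normalize_ingredient(name: str) -> str:
    """Uppercase, trim, collapse internal whitespace, map ``\\`` to ``/``.

    Combination products (e.g. ``NIRMATRELVIR\\RITONAVIR``) stay single
    tokens with ``/`` as the separator; no component-level expansion.
    """
    return _WS.sub(" ", name.replace("\\", "/").strip()).upper()


def extract_primary_suspect(
    records: Sequence[RawDrugRecord],
) -> Dict[str, FrozenSet[str]]:
    """Map each primaryid to its set of primary-suspect active ingredients.

    Only rows with ``role_cod == "PS"`` contribute; ``prod_ai`` is
    normalized via :func:`normalize_ingredient`; rows empty after
    normalization are ignored.
    """
    out: Dict[str, set] = defaultdict(set)
    for r in records:
        if r.role_cod is None or r.role_cod.strip().upper() != "PS":
            continue
        if r.prod_ai is None:
            continue
        name = normalize_ingredient(r.prod_ai)
        if name:
            out[r.primaryid].add(name)
    return {pid: frozenset(names) for pid, names in out.items()}


def _map_sex(code: Optional[str]) -> str:
    code = (code or "").strip().upper()
    if code == "F":
        return "female"
    if code == "M":
        return "male"
    return "unknown"


def build_case_table(
    demo: Sequence[RawDemoRecord],
    drug: Sequence[RawDrugRecord],
    reac: Sequence[RawReacRecord],
    *,
    single_ps_only: bool = True,
    provenance: Optional[Provenance] = None,
) -> CleanCaseTable:
    """Join filtered demo records with drug and reaction rows.

    ``demo`` must already be professional-filtered and deduplicated.
    Cases with no primary-suspect ingredient or no preferred term are
    excluded as missing essentials; with ``single_ps_only`` cases whose
    reports implicate more than one primary-suspect ingredient are also
    excluded (separately counted).  PT strings are trimmed and thereafter
    matched exactly, case preserved.
    """
    prov = provenance if provenance is not None else Provenance(raw_demo_rows=len(demo))

    ps_map = extract_primary_suspect(drug)
    n_ps_rows = sum(1 for r in drug if r.role_cod and r.role_cod.strip().upper() == "PS")
    prov.dropped_empty_prod_ai_rows += n_ps_rows - sum(len(v) for v in ps_map.values())

    pt_map: Dict[str, set] = defaultdict(set)
    for r in reac:
        if r.pt is None:
            continue
        pt = r.pt.strip()
        if pt:
            pt_map[r.primaryid].add(pt)

    cases: List[CleanCase] = []
    for d in demo:
        ingredients = ps_map.get(d.primaryid, frozenset())
        pts = pt_map.get(d.primaryid, set())
        if not ingredients or not pts:
            prov.dropped_missing_essentials += 1
            continue
        if single_ps_only and len(ingredients) > 1:
            prov.dropped_multi_ps += 1
            continue
        age_years = normalize_age(d.age, d.age_cod)
        if d.age is not None and age_years is None:
            prov.invalid_age_records += 1
        cases.append(
            CleanCase(
                caseid=d.caseid,
                primaryid=d.primaryid,
                sex=_map_sex(d.sex),
                age_years=age_years,
                reporter=(d.occp_cod or "").strip().upper() or None,
                ps_ingredients=frozenset(ingredients),
                pts=frozenset(pts),
            )
        )
    prov.retained += len(cases)
    return CleanCaseTable(cases, prov)


def preprocess_quarters(
    demo: Sequence[RawDemoRecord],
    drug: Sequence[RawDrugRecord],
    reac: Sequence[RawReacRecord],
    *,
    professional_only: bool = True,
    single_ps_only: bool = True,
) -> CleanCaseTable:
    """Run the full cleaning pipeline on raw record sequences.

    Applies the professional-reporter filter, per-case deduplication and
    :func:`build_case_table`, accumulating provenance so that every raw
    demo row is accounted for in exactly one bucket.
    """
    prov = Provenance(raw_demo_rows=len(demo))
    prov.quarters = tuple(sorted({d.quarter for d in demo if d.quarter}))

    if professional_only:
        professional = filter_professional(demo)
        prov.dropped_nonprofessional = len(demo) - len(professional)
    else:
        professional = list(demo)
    deduped = deduplicate_cases(professional)
    prov.dropped_duplicate_version = len(professional) - len(deduped)
    return build_case_table(deduped, drug, reac, single_ps_only=single_ps_only, provenance=prov)
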