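"""The two disproportionality analysis modes over a clean case table.

*Top reactions* profiles one drug group: rank its reactions by how many
exposed cases report them, then estimate, for each of the top k (default
15), the reporting odds ratio of the group against all other drugs.

*Reaction comparison* contrasts a target drug group with a control group
(a named group, or "OTHER DRUGS" — every case not exposed to the target)
on user-selected reactions, optionally stratified by sex or by an age
split (default 50 years, the split value itself belonging to the younger
stratum); stratified runs add a z-test comparison between the strata.

Cases exposed to both target and control groups are excluded from
two-group comparisons so the contingency cells stay disjoint; cases of
unknown sex or age are excluded from the respective stratified analysis.
All exclusions are counted in the report.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, FrozenSet, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .preprocess import CleanCase, CleanCaseTable, normalize_ingredient
from .stats import (
    ContingencyTable,
    RorResult,
    SubgroupComparison,
    UndefinedEstimateError,
    compare_subgroups,
    count_contingency,
    ror,
)

OTHER_DRUGS_LABEL = "OTHER DRUGS"


class EmptyCohortError(ValueError):
    """No case in the cohort is exposed to the requested drug group."""


@dataclass(frozen=True)
class DrugGroup:
    """A named set of active ingredients, or the all-other-drugs comparator."""

    name: str
    ingredients: FrozenSet[str] = frozenset()
    is_other_drugs: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "ingredients", frozenset(normalize_ingredient(i) for i in self.ingredients)
        )
        if not self.ingredients and not self.is_other_drugs:
            raise ValueError("a drug group needs at least one ingredient (or is_other_drugs)")

    @classmethod
    def of(cls, *ingredients: str, name: Optional[str] = None) -> "DrugGroup":
        label = name if name is not None else " + ".join(ingredients)
        return cls(name=label, ingredients=frozenset(ingredients))

    @classmethod
    def other_drugs(cls) -> "DrugGroup":
        return cls(name=OTHER_DRUGS_LABEL, is_other_drugs=True)

    def exposed(self, case: CleanCase) -> bool:
        return not self.ingredients.isdisjoint(case.ps_ingredients)


@dataclass(frozen=True)
class SubgroupSpec:
    """How to stratify an analysis: not at all, by sex, or by an age split."""

    mode: str = "none"  # none | sex | age
    age_split: float = 50.0

    def __post_init__(self):
        if self.mode not in ("none", "sex", "age"):
            raise ValueError(f"mode must be none, sex or age, got {self.mode!r}")
        if self.age_split <= 0:
            raise ValueError("age_split must be positive")

    def strata(self) -> List[Tuple[str, Callable[[CleanCase], bool]]]:
        """Named predicates for the two strata (empty in mode ``none``)."""
        if self.mode == "sex":
            return [
                ("female", lambda c: c.sex == "female"),
                ("male", lambda c: c.sex == "male"),
            ]
        if self.mode == "age":
            split = self.age_split
            return [
                (f">{split:g}y", lambda c: c.age_years is not None and c.age_years > split),
                (f"<={split:g}y", lambda c: c.age_years is not None and c.age_years <= split),
            ]
        return []


@dataclass
class ReportRow:
    """One estimated (or not-estimable) drug-group x reaction association."""

    drug_group: str
    pt: str
    stratum: Optional[str]
    table: ContingencyTable
    result: Optional[RorResult] = None
    error: Optional[str] = None

    @property
    def estimable(self) -> bool:
        return self.result is not None


@dataclass
class AnalysisReport:
    """Everything one analysis run produced, ready to tabulate or plot."""

    mode: str
    target: str
    comparator: str
    rows: List[ReportRow] = field(default_factory=list)
    comparisons: List[Tuple[str, Optional[SubgroupComparison], Optional[str]]] = field(
        default_factory=list
    )  # (pt, comparison or None, error message or None)
    frequency: List[Tuple[str, int]] = field(default_factory=list)  # all PTs of the target
    cohort_sizes: dict = field(default_factory=dict)
    excluded: dict = field(default_factory=dict)

    def forest_frame(self) -> pd.DataFrame:
        """Raw data behind the forest plot, one row per estimate."""
        recs = []
        for row in self.rows:
            rec = {
                "drug_group": row.drug_group,
                "pt": row.pt,
                "stratum": row.stratum or "",
                "a": row.table.a,
                "b": row.table.b,
                "c": row.table.c,
                "d": row.table.d,
            }
            if row.result is not None:
                r = row.result
                rec.update(
                    ror=r.ror,
                    ci_low=r.ci_low,
                    ci_high=r.ci_high,
                    corrected=r.corrected,
                    significant=r.significant,
                )
            else:
                rec.update(ror=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
                           corrected=False, significant=False)
                rec["error"] = row.error
            recs.append(rec)
        return pd.DataFrame(recs)

    def comparison_frame(self) -> pd.DataFrame:
        recs = []
        for pt, comp, err in self.comparisons:
            if comp is None:
                recs.append({"pt": pt, "error": err})
                continue
            recs.append(
                {
                    "pt": pt,
                    "stratum_1": comp.label_1,
                    "stratum_2": comp.label_2,
                    "ror_1": comp.r1.ror,
                    "ror_2": comp.r2.ror,
                    "fold": comp.fold,
                    "z": comp.z,
                    "p": comp.p,
                    "flagged": comp.flagged,
                }
            )
        return pd.DataFrame(recs)

    def frequency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.frequency, columns=["pt", "count"])


def top_reactions(
    cases: Union[CleanCaseTable, Sequence[CleanCase]],
    group: DrugGroup,
    k: int = 15,
) -> List[Tuple[str, int]]:
    """Top-k reactions of a drug group, ranked by exposed-case count.

    Each case contributes at most once per PT (PT sets are per-case);
    ties are broken alphabetically.  Raises :class:`EmptyCohortError` when
    no case is exposed.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    counts = _pt_counts(cases, group)
    if not counts:
        raise EmptyCohortError(f"no case exposed to drug group {group.name!r}")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def _pt_counts(cases, group: DrugGroup) -> Counter:
    counts: Counter = Counter()
    for case in cases:
        if group.exposed(case):
            counts.update(case.pts)
    return counts


def most_potential_reactions(
    cases: Union[CleanCaseTable, Sequence[CleanCase]],
    group: DrugGroup,
    k: int = 15,
) -> AnalysisReport:
    """Reaction profile of one drug group against all other drugs.

    The report carries the full PT frequency table of the group plus, for
    each of the top-k reactions, the ROR of the group versus all
    unexposed cases.  Reactions whose comparator is degenerate (e.g. the
    group covers the whole cohort) are recorded as not estimable.
    """
    full = sorted(_pt_counts(cases, group).items(), key=lambda kv: (-kv[1], kv[0]))
    if not full:
        raise EmptyCohortError(f"no case exposed to drug group {group.name!r}")
    top = full[:k]
    n_exposed = sum(1 for c in cases if group.exposed(c))
    report = AnalysisReport(
        mode="most_potential_reactions",
        target=group.name,
        comparator=OTHER_DRUGS_LABEL,
        frequency=full,
        cohort_sizes={"cohort": len(list(cases)), "exposed": n_exposed},
    )
    for pt, _count in top:
        table = count_contingency(cases, set(group.ingredients), pt)
        row = ReportRow(drug_group=group.name, pt=pt, stratum=None, table=table)
        try:
            row.result = ror(table)
        except UndefinedEstimateError as exc:
            row.error = str(exc)
        report.rows.append(row)
    return report


def reaction_comparison(
    cases: Union[CleanCaseTable, Sequence[CleanCase]],
    target: DrugGroup,
    control: DrugGroup,
    pts: Sequence[str],
    sub: SubgroupSpec = SubgroupSpec(),
) -> AnalysisReport:
    """Compare selected reactions between a target and a control group.

    The cohort is target-exposed plus control-exposed cases (all cases
    when the control is OTHER DRUGS); cases exposed to both groups are
    excluded and counted.  In subgroup mode each stratum gets its own
    ROR (the whole 2x2 table is restricted to the stratum, so the
    comparator cells are stratum-specific too) and the strata are
    compared with the z-test; a stratum with no exposed cases marks that
    reaction's comparison not-estimable without affecting the others.
    """
    if not pts:
        raise ValueError("pts must be non-empty")
    pts = [p.strip() for p in pts]

    all_cases = list(cases)
    if control.is_other_drugs:
        cohort = all_cases
        n_both = 0
    else:
        cohort = []
        n_both = 0
        for c in all_cases:
            t, u = target.exposed(c), control.exposed(c)
            if t and u:
                n_both += 1
            elif t or u:
                cohort.append(c)

    report = AnalysisReport(
        mode=f"reaction_comparison[{sub.mode}]",
        target=target.name,
        comparator=control.name,
        excluded={"exposed_to_both": n_both},
        frequency=sorted(_pt_counts(cohort, target).items(), key=lambda kv: (-kv[1], kv[0])),
    )
    report.cohort_sizes["cohort"] = len(cohort)

    group = set(target.ingredients)
    strata = sub.strata()
    if not strata:
        for pt in pts:
            table = count_contingency(cohort, group, pt)
            row = ReportRow(drug_group=target.name, pt=pt, stratum=None, table=table)
            try:
                row.result = ror(table)
            except UndefinedEstimateError as exc:
                row.error = str(exc)
            report.rows.append(row)
        return report

    in_any = strata[0][1]
    in_other = strata[1][1]
    n_unknown = sum(1 for c in cohort if not in_any(c) and not in_other(c))
    report.excluded[f"unknown_{sub.mode}"] = n_unknown
    for label, pred in strata:
        report.cohort_sizes[label] = sum(1 for c in cohort if pred(c))

    for pt in pts:
        per_stratum = {}
        for label, pred in strata:
            table = count_contingency(cohort, group, pt, cohort_filter=pred)
            row = ReportRow(drug_group=target.name, pt=pt, stratum=label, table=table)
            try:
                row.result = ror(table)
            except UndefinedEstimateError as exc:
                row.error = str(exc)
            report.rows.append(row)
            per_stratum[label] = row
        r1, r2 = (per_stratum[label] for label, _ in strata)
        if r1.estimable and r2.estimable:
            comp = compare_subgroups(r1.result, r2.result, labels=(r1.stratum, r2.stratum))
            report.comparisons.append((pt, comp, None))
        else:
            bad = ", ".join(r.stratum for r in (r1, r2) if not r.estimable)
            report.comparisons.append((pt, None, f"not estimable in stratum {bad}"))
    return report


def write_report(
    report: AnalysisReport,
    out_dir: Union[str, Path],
    stem: str = "analysis",
    image_formats: Sequence[str] = ("png", "svg"),
    excel: bool = False,
) -> List[Path]:
    """Write the four analysis artifacts to *out_dir*.

    Mirrors the downloadable outputs of an interactive run: a pie chart
    of the target group's reaction frequencies, a forest plot of the
    estimated RORs, the full frequency table and the forest raw-data
    table (tab-separated; optionally also as a spreadsheet).  Returns the
    written paths.
    """
    from .viz import forest_rows_from_report, render_forest, render_pie

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    freq = report.frequency_frame()
    path = out_dir / f"{stem}_frequency.tsv"
    freq.to_csv(path, sep="\t", index=False)
    written.append(path)

    forest = report.forest_frame()
    path = out_dir / f"{stem}_forest_data.tsv"
    forest.to_csv(path, sep="\t", index=False)
    written.append(path)

    comp = report.comparison_frame()
    if not comp.empty:
        path = out_dir / f"{stem}_subgroup_comparison.tsv"
        comp.to_csv(path, sep="\t", index=False)
        written.append(path)

    if excel:
        path = out_dir / f"{stem}_tables.xlsx"
        with pd.ExcelWriter(path) as xls:
            freq.to_excel(xls, sheet_name="frequency", index=False)
            forest.to_excel(xls, sheet_name="forest_raw_data", index=False)
            if not comp.empty:
                comp.to_excel(xls, sheet_name="subgroup_comparison", index=False)
        written.append(path)

    top15 = report.frequency[:15]
    if top15:
        for fmt in image_formats:
            path = out_dir / f"{stem}_pie.{fmt}"
            render_pie(top15, path)
            written.append(path)
    rows = forest_rows_from_report(report)
    if rows:
        for fmt in image_formats:
            path = out_dir / f"{stem}_forest.{fmt}"
            render_forest(rows, path)
            written.append(path)
    return written
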