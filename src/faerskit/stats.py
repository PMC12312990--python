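"""Reporting-odds-ratio disproportionality statistics.

For a drug group A and an adverse reaction j, reports in the cohort are
cross-classified into the 2x2 table

====================  ==========  ==============
..                    reaction j  not reaction j
====================  ==========  ==============
exposed to A          a           b
not exposed to A      c           d
====================  ==========  ==============

and the reporting odds ratio is ``ROR = (a/b) / (c/d)``, with Wald
standard error on the log scale ``SE(ln ROR) = sqrt(1/a + 1/b + 1/c +
1/d)`` and 95% CI ``exp(ln ROR +/- 1.96 * SE)``.  If any cell is zero the
Haldane–Anscombe continuity correction adds 0.5 to all four cells first;
nonzero tables stay exact.

A signal is flagged when the lower bound of the log2-transformed 95% CI
is above zero — equivalently, when the lower CI bound exceeds 1 on the
natural scale, which is how it is implemented.

Two subgroups (e.g. female vs male, or older vs younger than an age
split) are compared with a z-test on the log RORs,

    z = (ln ROR1 - ln ROR2) / sqrt(SE1^2 + SE2^2),
    p = 2 * (1 - Phi(|z|)),

with Phi the standard-normal CDF, computed through the complementary
error function.  The subgroup difference is flagged when the ROR fold
ratio is at least 1.5 *and* p < .05 — both conditions are required.

No multiple-testing adjustment is applied anywhere: every p-value and
significance flag is per-comparison, as is conventional for
hypothesis-generating disproportionality screens.  Treat flagged signals
as leads, not confirmed effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Set, Tuple

from .preprocess import CleanCase, normalize_ingredient

Z_95 = 1.96  # fixed multiplier of the Wald interval

SUBGROUP_FOLD_THRESHOLD = 1.5
SUBGROUP_ALPHA = 0.05


class UndefinedEstimateError(ValueError):
    """The ROR is undefined for this table (no exposed or no unexposed cases)."""


@dataclass(frozen=True)
class ContingencyTable:
    """The four report counts for one drug group x one reaction."""

    a: int  # exposed, with reaction
    b: int  # exposed, without reaction
    c: int  # unexposed, with reaction
    d: int  # unexposed, without reaction

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_unexposed(self) -> int:
        return self.c + self.d

    @property
    def cohort_size(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> Tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class RorResult:
    """Point estimate, log-scale SE, 95% CI and significance flag."""

    ror: float
    ln_ror: float
    se_ln: float
    ci_low: float
    ci_high: float
    corrected: bool
    significant: bool


@dataclass(frozen=True)
class SubgroupComparison:
    """z-test between the RORs of two independent strata."""

    label_1: str
    label_2: str
    r1: RorResult
    r2: RorResult
    fold: float
    z: float
    p: float
    flagged: bool


def phi(x: float) -> float:
    """Standard-normal CDF via the complementary error function."""
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


def count_contingency(
    cases: Iterable[CleanCase],
    drug_group: Set[str],
    pt: str,
    cohort_filter: Optional[Callable[[CleanCase], bool]] = None,
) -> ContingencyTable:
    """Cross-classify cohort cases by drug-group exposure and reaction.

    A case is *exposed* iff its primary-suspect ingredient set intersects
    ``drug_group`` (names normalized on entry); it *has the event* iff the
    trimmed ``pt`` is among its preferred terms.  The four cells partition
    the cohort (the cases passing ``cohort_filter``).  A reaction absent
    from the whole cohort is a valid table with a = c = 0.
    """
    if not drug_group:
        raise ValueError("drug_group must be non-empty")
    group = frozenset(normalize_ingredient(g) for g in drug_group)
    pt = pt.strip()
    a = b = c = d = 0
    for case in cases:
        if cohort_filter is not None and not cohort_filter(case):
            continue
        exposed = not group.isdisjoint(case.ps_ingredients)
        event = pt in case.pts
        if exposed:
            if event:
                a += 1
            else:
                b += 1
        elif event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def ror(table: ContingencyTable) -> RorResult:
    """Reporting odds ratio with Wald 95% CI for one 2x2 table.

    Zero cells trigger the Haldane–Anscombe correction (0.5 added to all
    four cells, ``corrected=True``); tables with no exposed or no
    unexposed cases raise :class:`UndefinedEstimateError`.  The flag
    ``significant`` is the forest criterion: lower CI bound above 1.
    """
    if table.n_exposed == 0 or table.n_unexposed == 0:
        raise UndefinedEstimateError(
            f"ROR undefined: exposed={table.n_exposed}, unexposed={table.n_unexposed}"
        )
    a, b, c, d = table.cells()
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    estimate = (a / b) / (c / d)
    ln_ror = math.log(estimate)
    se_ln = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    ci_low = math.exp(ln_ror - Z_95 * se_ln)
    ci_high = math.exp(ln_ror + Z_95 * se_ln)
    return RorResult(
        ror=estimate,
        ln_ror=ln_ror,
        se_ln=se_ln,
        ci_low=ci_low,
        ci_high=ci_high,
        corrected=corrected,
        significant=ci_low > 1.0,
    )


def compare_subgroups(
    r1: RorResult,
    r2: RorResult,
    labels: Tuple[str, str] = ("subgroup 1", "subgroup 2"),
) -> SubgroupComparison:
    """z-test on log RORs of two independent strata, with the 1.5-fold rule."""
    se = math.sqrt(r1.se_ln**2 + r2.se_ln**2)
    diff = r1.ln_ror - r2.ln_ror
    if se == 0.0:
        z = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        z = diff / se
    p = 2.0 * (1.0 - phi(abs(z)))
    hi, lo = max(r1.ror, r2.ror), min(r1.ror, r2.ror)
    fold = hi / lo if lo > 0 else math.inf
    return SubgroupComparison(
        label_1=labels[0],
        label_2=labels[1],
        r1=r1,
        r2=r2,
        fold=fold,
        z=z,
        p=p,
        flagged=(fold >= SUBGROUP_FOLD_THRESHOLD and p < SUBGROUP_ALPHA),
    )


def ci_consistency_check(ror_value: float, ci_low: float, ci_high: float) -> float:
    """Reconstruct the point estimate implied by a Wald CI.

    Wald intervals are geometrically symmetric about the estimate, so
    ``exp((ln L + ln U)/2)`` must reproduce the ROR a table prints from
    its CI bounds.  Useful for validating published (ROR, CI) triples;
    ``ror_value`` itself is not used in the computation and is accepted
    only for call-site readability.
    """
    if ci_low <= 0 or ci_high <= 0:
        raise ValueError("CI bounds must be positive")
    if ci_low > ci_high:
        raise ValueError("ci_low must not exceed ci_high")
    return math.exp(0.5 * (math.log(ci_low) + math.log(ci_high)))
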