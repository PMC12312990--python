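"""Seeded simulation studies validating the estimator's operating
characteristics.

Three studies, each runnable in well under the time of a coffee:

* **Subgroup-test null calibration** — two independent strata share a
  common true reporting odds ratio; the z-test comparing their estimated
  RORs should reject at about the nominal rate.
* **CI coverage under injected signals** — synthetic cohorts with a
  known drug–event ROR; the Wald 95% interval should cover the truth in
  about 95% of replicates.
* **Null signal-flag rate** — cohorts with no injected signal; the
  forest criterion (CI lower bound above 1) should flag only a small
  fraction of drug–reaction pairs (the Wald interval is mildly
  anti-conservative at small counts, so slightly above 2.5% per side is
  expected).

Stratum and cohort sizes default to the asymptotic regime of the Wald
z-test (expected cell counts well above 5); the studies characterize
the estimator there, not under sparse-data conditions.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .stats import ContingencyTable, compare_subgroups, ror
from .synth import Signal, SynthConfig, _draw_arrays, odds_adjust, signal_contingency


def subgroup_null_rejection_rate(
    n_replicates: int = 10_000,
    seed: int = 0,
    common_ror: float = 2.0,
    n_exposed: int = 1500,
    n_unexposed: int = 4500,
    background_p: float = 0.08,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the subgroup z-test under a two-stratum null.

    Both strata draw event counts from binomials sharing the same true
    ROR (``common_ror`` against ``background_p``); every p-value below
    ``alpha`` is a false rejection.  Returns the fraction rejected.
    """
    rng = np.random.default_rng(seed)
    p_exposed = odds_adjust(background_p, common_ror)
    rejected = 0
    for _ in range(n_replicates):
        tables = []
        for _stratum in range(2):
            a = int(rng.binomial(n_exposed, p_exposed))
            c = int(rng.binomial(n_unexposed, background_p))
            tables.append(ContingencyTable(a, n_exposed - a, c, n_unexposed - c))
        comp = compare_subgroups(ror(tables[0]), ror(tables[1]))
        if comp.p < alpha:
            rejected += 1
    return rejected / n_replicates


_RECOVERY_INGREDIENTS = (("DRUG_A", 0.30), ("DRUG_B", 0.35), ("DRUG_C", 0.35))
_RECOVERY_PTS = (("PT_BG1", 0.08), ("PT_BG2", 0.06), ("PT_BG3", 0.05), ("PT_SIGNAL", 0.05))


def recovery_config(true_ror: float, n_cases: int, seed: int) -> SynthConfig:
    """Study conditions for signal recovery: one injected drug–event pair
    on top of the generator's default demographics and messiness."""
    return SynthConfig(
        n_cases=n_cases,
        ingredients=_RECOVERY_INGREDIENTS,
        pts=_RECOVERY_PTS,
        signals=(Signal("DRUG_A", "PT_SIGNAL", true_ror),),
        seed=seed,
    )


def signal_ci_coverage(
    true_ror: float,
    n_replicates: int = 200,
    n_cases: int = 50_000,
    seed: int = 0,
) -> Tuple[float, float]:
    """CI coverage and mean estimate for one injected signal strength.

    Each replicate generates a cohort with the signal, estimates the ROR
    of the signal pair among retained cases, and checks whether the 95%
    CI covers ``true_ror``.  Returns ``(coverage, mean_estimate)``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    covered = 0
    estimates = []
    for s in seeds:
        config = recovery_config(true_ror, n_cases, int(s))
        table = signal_contingency(config, "DRUG_A", "PT_SIGNAL")
        result = ror(table)
        estimates.append(result.ror)
        if result.ci_low <= true_ror <= result.ci_high:
            covered += 1
    return covered / n_replicates, float(np.mean(estimates))


def null_signal_flag_rate(
    n_cohorts: int = 20,
    n_cases: int = 10_000,
    seed: int = 0,
    ingredient: str = "DRUG_A",
) -> float:
    """Fraction of drug–reaction pairs flagged significant with no signal.

    Across ``n_cohorts`` seeded cohorts generated without any injected
    association, every reaction is tested for ``ingredient`` with the
    forest criterion; returns the pooled flag fraction.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_cohorts) % (2**31)
    flagged = 0
    total = 0
    for s in seeds:
        config = SynthConfig(n_cases=n_cases, seed=int(s))
        arr = _draw_arrays(config)
        keep = arr["retained"]
        exposed = arr["ing_idx"] == arr["ing_names"].index(ingredient)
        for j in range(len(arr["pt_names"])):
            event = arr["member"][:, j]
            table = ContingencyTable(
                int(np.sum(keep & exposed & event)),
                int(np.sum(keep & exposed & ~event)),
                int(np.sum(keep & ~exposed & event)),
                int(np.sum(keep & ~exposed & ~event)),
            )
            total += 1
            if ror(table).significant:
                flagged += 1
    return flagged / total
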