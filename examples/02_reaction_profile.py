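"""Top-reaction profile of one drug versus all other drugs.

Simulates a cohort with one injected association (DRUG_A causes
Retinopathy with a true reporting odds ratio of 8), then ranks DRUG_A's
reactions and estimates each one's ROR against all other drugs.
"""

from faerskit import DrugGroup, Signal, SynthConfig, most_potential_reactions, simulate_case_table

config = SynthConfig(
    n_cases=20_000,
    seed=7,
    signals=(Signal("DRUG_A", "Retinopathy", ror=8.0),),
)
table = simulate_case_table(config)

report = most_potential_reactions(table, DrugGroup.of("DRUG_A"), k=10)
print(f"cohort {report.cohort_sizes['cohort']} cases, "
      f"{report.cohort_sizes['exposed']} exposed to DRUG_A\n")
print(f"{'reaction':<16}{'cases':>6}{'ROR':>8}{'95% CI':>18}  flagged")
for (pt, n), row in zip(report.frequency, report.rows):
    r = row.result
    mark = "*" if r.significant else ""
    print(f"{pt:<16}{n:>6}{r.ror:>8.2f}   ({r.ci_low:6.2f}, {r.ci_high:6.2f})  {mark}")
# The injected Retinopathy signal should be the only reaction whose CI
# lower bound exceeds 1 (flagged *); its ROR estimate should sit near 8.
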