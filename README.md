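# faerskit

Disproportionality analysis of FDA Adverse Event Reporting System
(FAERS) spontaneous reports: a complete, testable pipeline from the raw
quarterly ASCII dumps to reporting-odds-ratio forest plots and
demographic subgroup comparisons.

**Who it is for.** Pharmacovigilance researchers and clinical
epidemiologists who want to screen FAERS for drug–event signals — which
adverse reactions are reported disproportionately often for a drug, how
two drugs compare on selected reactions, and whether a signal differs
between women and men or across an age split — without hand-rolling the
ETL and 2×2 statistics every time.

## The statistics

For drug group *A* and reaction *j*, cohort reports are cross-classified
into a 2×2 table with counts *a* (exposed, with *j*), *b* (exposed,
without *j*), *c* (unexposed, with *j*), *d* (neither). The reporting
odds ratio and its Wald interval are

```
ROR = (a/b) / (c/d)
SE(ln ROR) = sqrt(1/a + 1/b + 1/c + 1/d)
95% CI     = exp(ln ROR ± 1.96 · SE)
```

with the Haldane–Anscombe correction (+0.5 to every cell) when any cell
is zero. A signal is flagged when the lower bound of the
log2-transformed 95% CI is above zero (equivalently, CI lower bound
> 1). Two strata are compared with

```
z = (ln ROR₁ − ln ROR₂) / sqrt(SE₁² + SE₂²),   p = 2·(1 − Φ(|z|))
```

and the difference is flagged when the ROR fold ratio is ≥ 1.5 **and**
p < .05. No multiple-testing adjustment is applied; flags are
hypothesis-generating leads, not confirmed effects.

**Cleaning rules** (each raw report row is accounted for in exactly one
provenance bucket): keep reports from health-care professionals (codes
HP/MD/OT/PH); keep only the latest version of each case; take active
ingredients with role code PS (primary suspect); drop cases missing a
suspect ingredient or a MedDRA preferred term (PT); by default restrict
to single-suspect-drug reports. Ages are normalized to years from the
FAERS unit codes (DEC/YR/MON/WK/DY/HR).

## Worked example

`examples/02_reaction_profile.py` simulates a 20,000-case cohort with
one injected association — DRUG_A causes Retinopathy with a true ROR of
8 — cleans it, and profiles DRUG_A against all other drugs:

```
cohort 17839 cases, 2125 exposed to DRUG_A

reaction         cases     ROR            95% CI  flagged
Nausea             576    0.98   (  0.88,   1.08)
Headache           497    1.02   (  0.92,   1.14)
Diarrhoea          421    1.10   (  0.98,   1.24)
Dizziness          369    1.08   (  0.96,   1.22)
Vomiting           328    0.94   (  0.83,   1.06)
Retinopathy        303    8.16   (  6.91,   9.62)  *
...
```

Reading it: 2,125 of the cleaned cases have DRUG_A as primary suspect;
Retinopathy is the only reaction whose CI excludes 1 (flagged `*`), and
its estimate 8.16 (6.91–9.62) covers the injected truth of 8. The
background reactions all sit near ROR 1, as they should.
`examples/03_subgroup_comparison.py` does the same for a female-specific
signal and recovers it through the sex-stratified z-test (female ROR
5.18 vs male 0.89, fold 5.85, p ≈ 1e-11, flagged).

## Command line

```sh
faerskit simulate --seed 1 --n-cases 10000 --out-dir raw/
faerskit preprocess --quarters-dir raw/ --out cases.tsv
faerskit top-reactions --cases cases.tsv --drug DRUG_A --k 15 --out-dir out/
faerskit compare --cases cases.tsv --target DRUG_A --pt Retinopathy \
         --subgroup age --age-split 50 --out-dir out/
```

Each analysis run writes four artifacts: pie chart and forest plot
(PNG + SVG), the full PT frequency table and the forest raw-data table
(TSV; `--excel` adds a spreadsheet).

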