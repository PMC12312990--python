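# Methods

## The estimand and its estimator

Spontaneous-report databases have no denominator of drug users, so
"risk" is not identifiable; what is identifiable is *disproportionality*
of reporting. For a drug group *A* and MedDRA preferred term *j* the
reporting odds ratio compares the odds of reaction *j* among reports of
*A* with the same odds among all other reports (or a named control
group). The estimator is the sample odds ratio of the 2×2 case count
table, with Wald standard error `sqrt(1/a + 1/b + 1/c + 1/d)` on the
natural-log scale and a fixed 1.96 multiplier for the 95% interval.
Counting is per *case*: a case contributes at most once to any cell,
however many drug or reaction rows it carried.

**Zero cells.** When any cell is zero, 0.5 is added to all four cells
(Haldane–Anscombe), the standard pharmacovigilance convention; nonzero
tables are left exact, and the `corrected` flag records which branch
ran.

**Forest significance.** The screening criterion is "lower bound of the
log2-transformed 95% CI above zero". Implementation uses the
mathematically identical `ci_low > 1` on the natural scale, avoiding a
second transform.

**Subgroup comparison.** Two independent strata (female/male, or
above/below an age split) are compared with
`z = (ln ROR₁ − ln ROR₂)/sqrt(SE₁² + SE₂²)` and
`p = 2(1 − Φ(|z|))`, Φ computed through the complementary error
function (`erfc`), not a table; p-values are carried at machine
precision and displayed to 3 significant digits. The difference is
flagged only when the fold ratio `max(ROR)/min(ROR)` is at least 1.5
*and* p < .05 — the conjunction guards against flagging tiny but
precisely estimated differences. In stratified runs the *entire* 2×2
table is restricted to the stratum, so the comparator cells are
stratum-specific too; this makes the two strata independent, which the
z-test assumes. (An alternative — stratifying only the exposed arm —
would correlate the strata through the shared comparator.)

**No multiplicity adjustment.** None is applied anywhere, matching
screening practice; every flag is per-comparison and
hypothesis-generating.

## Cleaning rules and their order

1. *Professional filter*: keep occupation codes HP, MD, OT, PH
   (case-insensitive); consumers, blanks and unknown codes drop.
2. *Deduplication*: per caseid keep the maximal `caseversion` (absent
   version counts as 0 so any explicit version supersedes it); ties
   break by maximal primaryid compared after left-zero-padding — a
   deterministic, order-independent rule.
3. *Primary suspect extraction*: only role code PS rows; ingredient
   strings are uppercased, whitespace-collapsed, and `\` is normalized
   to `/` so combination products (e.g. NIRMATRELVIR/RITONAVIR) remain
   single tokens. No component-level expansion and no MedDRA synonym
   resolution: PTs are matched by exact trimmed string.
4. *Missing essentials*: cases with no suspect ingredient or no PT
   drop.
5. *Single-suspect restriction* (`single_ps_only`, default on): cases
   implicating more than one PS ingredient drop into their own
   provenance bucket. The default mirrors cohort definitions built on
   single-drug reports; turn it off to keep multi-suspect cases.

Every raw demo row lands in exactly one of the five buckets
(`Provenance.conserved()`), so exclusions are auditable and the
synthetic generator's manifest can predict retention exactly.

**Ages** convert to years with DEC×10, YR×1, MON÷12, WK÷52.1775
(weeks per Julian year), DY÷365.25, HR÷8766, rounded to 4 decimals;
results above 120 years or with unrecognized codes are treated as
missing. Cases of unknown age or sex stay in unstratified analyses and
are excluded (and counted) only from the corresponding stratified one.
The age split value itself belongs to the younger (≤) stratum.

## The synthetic generator

Each case draws: one primary-suspect ingredient (categorical exposure
mix), sex (55% F / 40% M / 5% unknown, the female skew typical of
spontaneous reporting), age from a normal(58, 18) clipped to
[0.5, 100] years — expressed in a mixture of FAERS unit codes (86% YR,
plus DEC/MON/WK/DY/HR) to exercise unit conversion — a reporter
occupation (90% professional, 8% consumer, 2% blank), and a reaction
set: independent Bernoulli draws per PT at its background probability.

**Signal injection.** For an injected (ingredient, PT, ρ) signal,
exposed cases draw that PT with probability `p' = ρ·o/(1+ρ·o)` where
`o` is the background odds — exactly the probability that makes the
population ROR against the all-other-drugs comparator equal ρ.
Sex- or age-specific variants override ρ per stratum.

**Guaranteed baseline reaction.** Every case additionally draws one PT
from the *non-signal* background terms. Real reports always carry at
least one reaction; without the guarantee, dropping zero-reaction cases
as "missing essentials" would condition the cohort on the number of
reactions drawn and bias signal RORs away from their injected values.
Because the guaranteed draw never selects a signal PT, injected odds
ratios stay exact in the population (verified empirically: mean
estimate 5.03 over replicates at ρ = 5).

**Messiness.** 5% of cases get a superseded earlier version (same
caseid, lower caseversion, one optional field degraded) so
deduplication is observable; 12%/5%/1% of cases lose age/sex/ingredient
to missingness; 30% carry a concomitant (role C) drug row that the PS
filter must ignore. All knobs are per-config; the same config and seed
give byte-identical files.

**What it does not emulate** (and what passing tests therefore do not
show about real FAERS): PT co-occurrence structure (draws are
independent given exposure), cross-caseid duplicates, reporting-delay
and stimulated-reporting dynamics, realistic MedDRA vocabularies,
indication-channeling confounding. Tests validate the *estimator and
pipeline*, not the epidemiology of any real drug.

## Validation studies and problem sizes

* *Formula oracle*: all 1,296 2×2 tables with cells 1–6, compared
  against a 50-digit `decimal` evaluation; observed worst relative
  error ~1e-15.
* *Published-triple reconstruction*: Wald CIs are geometrically
  symmetric about the estimate, so `exp((ln L + ln U)/2)` reproduces a
  printed ROR from its printed CI bounds to the printed precision;
  checked on five benchmark triples from large-scale FAERS analyses.
* *Null calibration*: 10,000 replicates of two strata sharing true
  ROR 2 (1,500 exposed / 4,500 unexposed per stratum, background
  probability 0.08 — expected cell counts comfortably in the Wald
  asymptotic regime). Rejection rate at α=.05 observed ≈ 0.049.
* *Coverage*: injected ρ ∈ {2, 5, 20}, 200 replicates × 50,000 cases
  (three-ingredient exposure mix with 30% on the signal drug, signal PT
  background 0.05, default demographics and messiness); 95% CI coverage
  observed 0.91–0.96.
* *Accounting*: two 2,000-case quarters with 8% duplicate versions;
  retained caseids must equal the manifest's prediction exactly.

These sizes keep the full validation under a minute on one core while
leaving Monte-Carlo error well inside the asserted bands.

## Numerical and interface choices

* 1.96 is a fixed constant, not a configurable quantile — the interval
  is defined as the 95% Wald interval.
* Undefined estimates (no exposed or no unexposed cases in the cohort)
  raise a typed error at the stats layer; analysis reports catch it and
  carry a not-estimable row rather than omitting the reaction.
* Top-k ranking counts exposed *cases* per PT (identical to counting
  mentions after per-case de-duplication); ties break alphabetically.
* Cases exposed to both target and control groups are excluded from
  two-group comparisons (counted in the report) so the table cells stay
  disjoint.
* File parsing is header-driven with case-insensitive column matching,
  `$` delimiter without quoting (embedded `$` is out of contract), and
  UTF-8 with latin-1 fallback; file kind is always stated by the
  caller, never sniffed. Quarter coverage is a runtime parameter.
* The CLI matches drug/PT names case-insensitively after normalization
  and, on a miss, suggests vocabulary entries containing the query as a
  substring; suggestions are advisory only.

## Known limitations

Disproportionality is not risk: RORs inherit all reporting biases
(underreporting, media-driven spikes, channeling). The Wald interval is
mildly anti-conservative at small counts — visible as a null flag rate
slightly above the per-side nominal 2.5% and CI coverage a little below
95% at extreme RORs. Duplicate detection is within-caseid only;
probabilistic record linkage across caseids is out of scope, as are the
other FAERS tables (OUTC, RPSR, THER, INDI) and time-to-onset analyses.
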