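# Methods

## Problem and scope

`pvdispro` implements a disproportionality-based pharmacovigilance
analysis of a spontaneous reporting system, configured by default for the
quinolone-antibiotic / pemphigoid drug–event pair. A spontaneous-report
database (FAERS-style quarterly DEMO/DRUG/REAC/THER tables) contains one
row per *report version*; versions of the same case share a CASEID. The
analysis asks whether reports naming a given drug as primary suspect
mention the target event more often than the rest of the database, using
three classical measures on the 2×2 table

|                | target event | other events |
|----------------|--------------|--------------|
| target drug    | a            | b            |
| all other drugs| c            | d            |

with N = a+b+c+d.

## Statistics

* **ROR** = (a/b)/(c/d) = ad/bc, with the log-scale Wald interval
  exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)). The constant 1.96 is used
  literally (not the exact normal quantile), matching the convention in
  which these formulas are printed.
* **PRR** = (a/(a+b))/(c/(c+d)). The default interval uses
  se² = 1/a + 1/(a+b) + 1/c + 1/(c+d), the form printed alongside the
  definition in this analysis tradition; the usual delta-method variance
  (1/a − 1/(a+b) + 1/c − 1/(c+d)) is available via `prr_ci="standard"`
  and is strictly narrower. Accompanying χ² is the Yates-corrected
  Pearson statistic in its classical shortcut form
  N(|ad−bc| − N/2)²/((a+b)(c+d)(a+c)(b+d)), evaluated without clamping
  (so exact independence gives a small positive value, e.g. 0.2 for
  a=b=c=d=5); plain Pearson is available via `chi2_correction="none"`.
* **BCPNN information component** IC = log₂(aN/((a+b)(a+c))). Posterior
  moments use the closed-form approximation of Bate et al. (1998) with
  priors α₁=β₁=1, α=β=2, γ₁₁=1 and
  γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)); IC025 = E(IC) − 2·√(V(IC)).
  The closed form (rather than Monte-Carlo posterior sampling) was chosen
  because it is the standard published expression consistent with the
  IC025 definition used here; at large counts IC025 → IC.

**Signal criteria** (evaluated independently; a pair is a signal if any
one fires): ROR — a ≥ 3 and lower 95% bound > 1; PRR — a ≥ 3, PRR ≥ 2 and
χ² ≥ 4; BCPNN — IC025 > 0 (strict). No multiple-testing adjustment is
applied, matching standard practice for these threshold rules; flag
counts are reported per metric.

**Zero cells.** By default a statistic touching an empty cell is reported
undefined (NaN) and flagged non-computable rather than corrected;
Haldane–Anscombe +0.5 on all cells is opt-in (`zero_cell="haldane"`)
because corrections change estimates and should be a visible choice.

**Stratified analysis.** Subgroups (age bands 18–44/45–64/≥65 plus <18
and NS; sex; reporter = healthcare professional {MD, PH} vs non-HCP vs
NS) are each analysed as their own 2×2 universe: the comparator is
restricted to the same stratum, the interpretation under which a
subgroup signal reflects within-stratum disproportionality rather than
between-stratum reporting volume. Strata with a < 3 are reported but
marked non-evaluable for the case-count-gated criteria.

## Pipeline conventions

* **Deduplication** keeps, per CASEID, the version with the largest
  PRIMARYID (numeric comparison; (length, lexicographic) fallback for
  non-numeric identifiers). FDA_DT is carried but does not decide
  retention. The operation is idempotent and invariant to row order, and
  runs on the whole database before any event restriction.
* **Dates** are YYYYMMDD. Partial dates (4–7 digits) are missing for any
  day-level arithmetic but a year prefix still populates the report
  year; this avoids fabricating day-level precision.
* **Units**: age decades ×10, months ÷12, days ÷365.25; weight lbs
  ×0.45359237. Unknown codes for sex/occupation/outcome normalise to NS,
  which is a first-class level in every summary.
* **Drug standardization** is exact case/whitespace-insensitive lookup in
  a configurable synonym dictionary (bundled: 5 included quinolones, 3
  excluded via `include: false`); unmapped names pass through flagged.
  No fuzzy matching and no licensed dictionary content.
* **Approval windows**: for drug D the entire 2×2 universe (both
  margins) is restricted to reports received on/after D's approval date,
  so exposed and comparator reports cover the same reporting period.
* **Percentages** round half-up (one decimal in profiles, two in
  time-to-onset), the convention under which 42/183 prints as 23.0;
  banker's rounding would disagree at exactly these boundary cases.
* **Time-to-onset**: latency = event onset − earliest therapy start of
  the suspect drug (first exposure defines induction time), in closed
  integer-day bins [0,30], [31,60], [61,90], [91,359], [360,∞). The
  91–359 bin makes the partition total so percentages can sum to 100.
  The denominator is records with computable latency; missing/partial
  dates and negative differences are excluded and counted in an
  exclusion log.
* **Concordance** with published cases is descriptive only: paired
  values and absolute differences per dimension (top-3 drug share, ≥65
  share, <45 share, female share, hospitalization rate, latency
  median/range); percentage dimensions diverging by more than 25 points
  (configurable) are flagged. The even-n latency median is the mean of
  the central pair. No inferential test is attached.

## Synthetic data generator

The generator emulates the study conditions of a quinolone–pemphigoid
reporting cohort so every stage is testable without downloads. Each case
is independently exposed to each drug with its background probability
(defaults 0.2–3% across the five quinolones); exposed drugs are listed
as primary suspects (verbatim name drawn uniformly from canonical +
synonyms). The target event occurs with probability `event_base_rate`
(default 0.01) times the maximum relative risk among exposed drugs;
`relative_risk = 1` is the null. Default relative risks (2.75, 2.31,
2.53, 1.0, 25.14) mirror the reported signal pattern of the studied
cohort. Demographic level frequencies and per-field missingness mirror
the observed NS shares of that cohort (e.g. weight missing 72.7%);
latency is log-normal with median 14 days and σ = 0.8, so most onsets
fall within 30 days; receipt years are uniform over 2004–2024 (no
reporting-trend model). About 10% of cases emit a superseded earlier
version with smaller PRIMARYID, earlier FDA_DT and sparser demographics;
the final version is ground truth. RNG streams are split per table from
the master seed, so equal seeds give byte-identical files.

What the generator does *not* emulate: reporting trends over time,
country-level dynamics, correlated polypharmacy, indication channeling,
duplicate cases with *different* CASEIDs, and free-text coding noise
beyond synonym substitution. Passing calibration tests therefore show
the estimator and criteria behave correctly under a clean independence
model — not that real FAERS signals are unbiased.

A quirk worth knowing: because several drugs carry elevated risks
simultaneously, the comparator ("all other reports") is slightly
event-enriched, attenuating each drug's ROR below the odds-ratio
analogue of its own configured relative risk — the same masking
phenomenon seen in real databases.

The literature-case generator uses largest-remainder quota allocation
for categorical fields so a small-n profile is realised exactly (7/9
elderly, not just in expectation); the bundled 9-case table is a
synthetic stand-in constructed to match the published case-series
marginals (77.8% ≥65, 55.6% female, 55.6% hospitalized, latency median
18 d, range 4–30 d, 7/9 on the three dominant drugs).

## Operating characteristics measured

Problem sizes were chosen to give stable Monte-Carlo estimates at
interactive runtimes: 200 replicates of 50,000 raw versions for null
calibration (observed ROR-signal rate ≈ 1.5%, well under the 5% bound;
two-sided 95% CI coverage of the null ≥ 94%), 100 replicates for
recovery (median ROR ≈ 5.1 against an injected relative risk of 5,
odds-ratio analogue ≈ 5.2), and 25 replicates for the sex-stratified
recovery of a female-only effect. These are recomputed by the test suite
and by `scripts/acceptance.py`; no number in this note is asserted
anywhere without being recomputed there.

## Known limitations

* The headline real-data disproportionality estimates of the studied
  cohort (e.g. ofloxacin ROR 2.75) require the full ~19M-report FAERS
  corpus and its unpublished b/c/d cells; they are not reproducible from
  printed counts and are not asserted. The package instead reproduces
  every proportion that *is* computable from printed counts and verifies
  estimator behaviour on synthetic ground truth.
* Exact preferred-term lists and the identities of the three excluded
  quinolones are configuration, not code; defaults are documented
  stand-ins.
* The event-term match is exact (case-insensitive); MedDRA hierarchy
  traversal is out of scope.
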