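# pvdispro

Disproportionality-based pharmacovigilance analysis of FAERS-style
spontaneous reports, configured by default for the quinolone-antibiotic /
pemphigoid drug–event pair.

Spontaneous reporting systems such as the FDA Adverse Event Reporting
System (FAERS) collect suspected adverse drug reaction reports as
quarterly "$"-delimited tables (DEMO, DRUG, REAC, THER). Signal
detection asks whether a drug–event pair is reported disproportionately
often: from the 2×2 table (a = drug & event, b = drug only, c = event
only, d = neither) one computes

* the **reporting odds ratio** ROR = (a/b)/(c/d) with
  95% CI = exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)),
* the **proportional reporting ratio** PRR = (a/(a+b))/(c/(c+d)) with a
  Yates-corrected Pearson χ²,
* the **BCPNN information component** IC = log₂(aN/((a+b)(a+c))) with
  the closed-form posterior bound IC025 = E(IC) − 2√(V(IC)),

and flags a signal when a ≥ 3 with ROR lower bound > 1, or a ≥ 3 with
PRR ≥ 2 and χ² ≥ 4, or IC025 > 0. `pvdispro` packages this analysis as a
tested pipeline: a synthetic FAERS-style generator with known ground
truth, FDA-style deduplication (largest PRIMARYID per CASEID), drug-name
standardization and approval-window cohort construction, the three
statistics with subgroup stratification, descriptive profiling,
time-to-onset binning, and a literature-concordance comparison. It is
aimed at pharmacoepidemiologists who want a reproducible, inspectable
version of this very common study design.

## Worked example

The statistical core is a statsmodels-style model/results pair:

```python
>>> from pvdispro import Disproportionality
>>> print(Disproportionality.from_counts(3, 97, 100, 9900).fit().summary())
Disproportionality analysis (2x2 spontaneous-report table)
==============================================================
  a=3  b=97  c=100  d=9900   N=10100
--------------------------------------------------------------
  ROR     3.0619   95% CI [  0.9544,   9.8231]   signal=False
  PRR     3.0000   95% CI [  0.9356,   9.6197]   chi2=  2.1923   signal=False
  IC      1.5567   E(IC)=  0.9717   IC025= -0.5255   signal=False
--------------------------------------------------------------
  any criterion met: False
```

Three cases and a three-fold ROR are not enough: the ROR interval still
crosses 1, χ² < 4, and the shrunken IC025 is negative — no criterion
fires. The full pipeline runs from one config:

```
pvdispro run-all --out runs/demo --seed 1
```

which simulates a 50,000-version synthetic quarterly extract whose
exposure rates, association strengths, demographics, missingness and
latency structure emulate the studied quinolone–pemphigoid cohort, then
deduplicates, builds per-drug cohorts, and writes `signals.csv`,
stratified signal tables, a clinical-characteristics profile,
time-to-onset tables and a literature-concordance table plus a JSON run
manifest. Stage-by-stage subcommands (`simulate`, `ingest`, `cohort`,
`signal`, `profile`, `tto`, `concordance`) expose the same steps for
real quarterly extracts.

Published summary counts are also first-class inputs. Feeding the
printed 183-report breakdown through the profiler:

```python
>>> from pvdispro import profile_from_counts
>>> profile_from_counts({"sex": {"F": 102, "M": 57, "NS": 24}})
  characteristic level  count  percent
0            sex     F    102     55.7
1            sex     M     57     31.1
2            sex    NS     24     13.1
```

i.e. 55.7% of the cohort's reports concern women, with 13.1% of reports
not stating sex — percentages recomputed from counts under half-up
one-decimal rounding.

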