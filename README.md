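# pvdisprop

Case/non-case disproportionality analysis for spontaneous adverse-drug-
reaction report databases, with a seeded synthetic-database simulator.

Pharmacovigilance databases such as VigiBase or FAERS collect millions of
individual case safety reports (ICSRs). A standard way to screen them for
safety signals — for example, drugs disproportionately reported with
*parosmia*, a distortion of smell perception — is the case/non-case
design: reports mentioning the target MedDRA Preferred Term (PT) are the
cases, all other reports are the non-cases, and for each drug the 2×2
table

|              | target PT | other PTs |
|--------------|-----------|-----------|
| exposed      | a         | b         |
| not exposed  | c         | d         |

is summarized by two statistics:

* **Reporting odds ratio** — ROR = (a/b)/(c/d), with the Wald 95%
  confidence interval exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)). The
  association is called significant when the lower bound exceeds 1. If any
  cell is zero, 0.5 is added to all four cells (Haldane–Anscombe, flagged).
* **Information component** — IC = log₂((O + 0.5)/(E + 0.5)) with observed
  O = a and expected E = (a+b)(a+c)/N, and its shrunk 95% credibility lower
  bound IC025 = IC − 3.3(O+0.5)^(−1/2) − 2(O+0.5)^(−3/2). A positive IC025
  constitutes a signal; the shrinkage damps small-count flukes that would
  inflate the ROR for rare PTs.

A report is *exposed* to a drug when any of its drug mentions carries the
suspect or interacting role (concomitant drugs do not count, configurable),
and it counts once per distinct exposure no matter how many matching
mentions it has. The package also produces the descriptive surface of a
report-series study: summary tables with explicit denominator policies
(all cases vs. available values only), chi-square / t-test stratified
comparisons, yearly trend counts, and ATC-class rollups.

Because the real databases are access-restricted, `pvdisprop` ships a
generative simulator (`pvdisprop.synthetic`) that emulates their structure
— multi-drug reports with roles, a rare target PT, planted drug–PT
reporting-rate ratios of known strength λ, demographics, seriousness,
outcomes and a vaccine-era reporting surge — so every stage of the pipeline
is testable against known ground truth.

Intended users: pharmacoepidemiologists and methodologists who want a
transparent, reproducible reference implementation of ROR/IC signal
screening, and a calibrated sandbox for studying its operating
characteristics.

## Worked example

```python
import pvdisprop as pv
from pvdisprop.cli import render_signal_table

db, truth = pv.generate(pv.default_parosmia_scenario(n_reports=200_000,
                                                     seed=7))
print("reports:", db.n_total, "| parosmia cases:",
      len(db.case_ids("Parosmia")))
sig = pv.signal_table(db, "Parosmia", min_cases=20)
print(render_signal_table(sig).to_string(index=False))
```

prints

```
reports: 200000 | parosmia cases: 263
Active Ingredient  ROR     95% CI Number of Cases (%)
      Flunisolide 87.5 63.9–119.8           52 (19.8)
       Lisinopril  1.7    1.1–2.5            25 (9.5)
```

The flunisolide analogue carries the strongest planted rate ratio
(λ = 150) and is recovered with 52 of the 263 parosmia cases and an ROR of
87.5 whose interval excludes 1 by a wide margin. The lisinopril row is
instructive: no effect was planted for it (λ = 1), yet at this seed it
clears the IC025 bar — a reminder that disproportionality flags are
screening statistics, not causal findings, and why published analyses also
impose a minimum case count. Rarer planted signals (e.g. the COVID-19
vaccine group, λ ≈ 2.3–3.3) sit below the IC025 threshold at this database
size; they emerge as the simulated database grows.

The descriptive side, from the same database:

```python
s = pv.summarize_cases(db, "Parosmia")
s["sex"].rows.set_index("label").loc["female", "percent"]   # 62.0
s["age"].median                                             # 48.3
pv.yearly_trend(db, "Parosmia", split="COVID-19 vaccine").tail(2)
#  year  in_group  other
#  2020         1      5
#  2021        45      9
```

The vaccine-group surge is confined to the launch years, as configured in
the scenario.

A shell interface mirrors the library:

```sh
pvdisprop simulate --out db/ --seed 3 --n-reports 100000
pvdisprop disprop --in db/ --pt Parosmia --min-cases 30
pvdisprop run --config run.yaml     # simulate → summarize → disprop → trend
```

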