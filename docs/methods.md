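# Methods

## The case/non-case design

Given a report database of N ICSRs, a target Preferred Term, and an
exposure definition (one drug, a named drug group, or an ATC prefix), the
package cross-classifies every report by case status (lists the target PT
at least once) and exposure status (has at least one matching drug mention
in an allowed role). Counting is report-level on both margins: a report
with the same drug mentioned twice, or with two drugs of the same ATC
class, contributes once. Non-cases are all remaining reports in the
database — no matching or restriction is applied. The cells (a, b, c, d)
therefore always partition N, and a + c equals the PT's case total; both
identities are asserted on every table build.

Exposure roles default to {suspect, interacting}. Concomitant medication
is background therapy, not a putative cause, and is excluded from the
exposure margin; the role filter is a parameter so sensitivity analyses
can widen it.

## Signal statistics

**ROR.** ROR = (a/b)/(c/d) with the Wald interval
exp(ln ROR ± z·√(1/a + 1/b + 1/c + 1/d)). The normal quantile is fixed at
z = 1.96 (the convention of the published tables this design follows;
statsmodels' exact 1.95996 differs in the fourth decimal of the bounds and
is used as a cross-check in the tests, not as the implementation). When
any cell is zero, 0.5 is added to all four cells (Haldane–Anscombe) and
the result is flagged `zero_cell_corrected`; tables with all cells
positive are evaluated exactly, which keeps reconstruction of printed
tables faithful. "Significant" means lower bound > 1.

**IC.** IC = log₂((O + 0.5)/(E + 0.5)), O = a, E = (a+b)(a+c)/N, with the
shrunk credibility lower bound
IC025 = IC − 3.3(O+0.5)^(−1/2) − 2(O+0.5)^(−3/2). This is the standard
observed-to-expected shrinkage form used for signal detection on large
spontaneous-report databases; the offsets make every input finite, give
IC = 0 exactly when O = E, and guarantee IC025 < IC. A signal is IC025 > 0.
E uses report-level margins, consistent with the counting rule above;
whether a pair-level expectation would be preferable for multi-drug
reports is a known ambiguity of the design and is fixed here as
report-level. No multiplicity adjustment is applied beyond the IC025
criterion itself, matching standard practice; users scanning thousands of
drugs should interpret the expected false-positive share accordingly.

**Signal table.** One row per drug and per dictionary group label,
filtered to IC025 > 0 and a minimum exposed-case count (default 30),
ranked by case count with alphabetical tie-break. Each row reports the
case count as a percentage of all cases; drugs belonging to a group also
report their share of the group's case count, the convention of published
vaccine-group tables.

**Implied-table reconstruction.** Published signal tables print a and the
point ROR but not b. Given also the case total and N,
b = (N − cases)/(1 + ROR·c/a) and d follows; `implied_table` exposes this
so printed intervals can be re-derived and audited. Cells are kept
real-valued (not rounded to integers) — the printed ROR is itself rounded,
and rounding b would add a second layer of error.

## Descriptive layer

Summary tables carry an explicit `denominator_policy` because published
report-series tables mix two: seriousness, sex, country and reporter
qualification are percentages of **all** cases (unknowns are a visible
category), while outcome percentages are computed over reports with an
**available** outcome only. Age and time to onset are summarized as both
median (IQR) and mean ± SD; time to onset per report is the earliest
recorded onset among its exposed mentions. Percentages render half-up at
one decimal (Python's banker's rounding would turn 27.05 into 27.0);
internal values keep full precision.

Stratified comparisons (a drug group versus all other case reports) use
Pearson's chi-square without continuity correction for sex and
reporter-is-HCP (unknowns excluded), and the two-sample t-test for age —
pooled-variance by default with a Welch flag, since published methods
sections rarely state which was used. Yearly trends count case reports by
entry-date calendar year; unparseable dates land in an "unknown" bin
rather than being dropped, so trend sums always equal the case total.

One published inconsistency is deliberately not reproduced: the
recovering-outcome percentage among vaccine cases ("284 (25.2%)") does not
follow from its own printed denominator (284/2197 → 12.9%); the module
always computes the self-consistent value.

## Data model

Four normalized CSV tables (reports, report_drugs, report_reactions,
drug_dict) with strict UTF-8/comma/header dialect; list-valued dictionary
columns are semicolon-joined. Reports are many-to-many with drugs and
reactions, so a denormalized single file would either duplicate report
attributes or lose mentions. Dates are ISO-8601 strings and only the year
is used analytically. On load: duplicate (report_id, drug_id, role) and
(report_id, pt) rows collapse; unrecognized demographic/outcome levels map
to "unknown" with a warning count (invalid drug roles are a hard error —
the role drives the exposure definition); ages outside [0, 130] become
missing; foreign-key violations raise with the offending report ids.
Writing sorts rows canonically, so load∘write is identity up to row order
and pipeline re-runs are byte-identical.

## The simulator

`pvdisprop.synthetic.generate` draws, per report: a drug count from a
geometric distribution (mean 1.8, truncated to [1, 10] — spontaneous
reports typically name one or two drugs); distinct drugs without
replacement, weighted by catalog weights (Gumbel top-k); a role per
mention (concomitant fraction 0.25, interacting 0.05 of the rest); and
independent Bernoulli reactions per PT at baseline probability times the
largest planted rate ratio λ among the report's exposed drugs (capped at
1). Max-λ combination, rather than a product, keeps probabilities bounded
and the interpretation simple; it is a simulator convention, not an
empirical claim. Only suspect/interacting mentions carry effects, matching
the downstream exposure definition, so concomitant-only exposure is null
by construction.

Every report must have at least one reaction — a spontaneous report exists
*because* something was reported. This is implemented as exact sequential
conditional sampling (chain rule over PTs given "at least one success"),
which is distributionally identical to redrawing empty reports but runs in
bounded time. A consequence worth knowing: conditioning inflates each PT's
realized marginal by 1/P(any reaction), so catalogs should include enough
common filler PTs that this factor stays near 1 (the default scenario's
factor is ≈1.06).

Demographics (sex split, truncated-normal age on [0, 110], reporter
qualification, entry-year distribution) come from per-group profiles: a
report exposed to a member of a profiled group (e.g. "COVID-19 vaccine")
draws from that group's profile, which is how the vaccine-era surge and
the older/more-female/less-HCP-reported vaccine stratum are produced.
Outcome, seriousness and country are global categorical draws. All
randomness flows through one numpy Generator, so (config, seed) fixes the
database byte-for-byte; ages use inverse-CDF truncated-normal sampling on
that same stream for the same reason.

Catalog weights are *selection* weights: realized per-report inclusion
probability is ≈ E[#drugs]·wᵢ/Σw, so a catalog whose weights sum to the
mean drugs-per-report realizes each weight as that drug's approximate
marginal. `GroundTruth` records the planted λ map and the realized
exposure and exposed-case counts, enabling recovery tests without
re-deriving them from the tables.

**What the simulator does not model:** dependence between co-reported PTs
(dysgeusia co-occurring with parosmia is generated independently, since a
disproportionality query cannot constrain that dependence), notoriety
bias, duplicate submissions of the same clinical event, and time-varying
λ. Passing tests therefore show that the pipeline recovers known planted
structure under these idealized conditions — not that real-database
signals are unconfounded.

## Default scenario

`default_parosmia_scenario` is the documented reference configuration: 47
drugs (a 4-member COVID-19 vaccine group, six inhaled/nasal
corticosteroids, eight antibiotics, nicotine-dependence drugs, SNRIs/SSRIs,
incretin mimetics, and common null fillers), 17 PTs with the target
"Parosmia" at baseline 5×10⁻⁴, planted parosmia λ spanning 1.3–150 (the
strongest for the flunisolide analogue) plus hyposmia effects for the
secondary-PT query, ~65% female overall with an older, more-female,
consumer-reported vaccine stratum, and vaccine reports confined to
2020–2021 over a flat 2002–2021 background. At 10⁵–2×10⁵ reports the
realized parosmia case fraction is ≈1.2×10⁻³, within the intended
(2×10⁻⁴, 2×10⁻³) band.

## Problem sizes and numerical conventions

The test suite exercises calibration at the scale the statistics need, not
more: null calibration uses 20 seeds × 50,000 reports (≈400 drug-seed
tests of the significance rule), rate-ratio recovery 50 seeds × 200,000
reports, and oracle-equivalence suites 1,000 random tables at 10⁻¹⁰
relative tolerance. Ties in ranked tables break alphabetically;
percentages with a zero denominator are NaN rather than an error; empty
case sets yield empty (header-only) outputs rather than exceptions.

## Known limitations

Disproportionality on spontaneous reports inherits reporting bias,
under-reporting and confounding by indication; nothing here assesses
causality. The default IC025 penalty is a normal-approximation to the
gamma posterior quantile, slightly conservative at very small O; an exact
variant is available (`compute_ic(..., ic025_method="gamma")`). The loader
validates structure, not clinical plausibility (e.g. it will accept a
fatal outcome with a non-serious flag). MedDRA hierarchy handling is flat
PT strings; LLT→PT mapping and licensed hierarchy traversal are out of
scope.
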