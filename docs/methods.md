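# Methods

## Setting and data model

The package analyses spontaneous adverse-event reports in the
post-2012Q4 FAERS dialect: quarterly `$`-delimited tables DEMO
(demographics, event and report dates), DRUG (drug name, active
ingredient, role code, indication), REAC (MedDRA preferred terms, PT),
OUTC (outcome codes DE/DS/HO/LT/OT) and THER (therapy start dates),
joined on `primaryid`. A case (`caseid`) may appear as several report
versions, possibly in different quarters; one report per case is kept —
the numerically largest `primaryid`, which encodes case number plus
version, so largest = latest. This tie-break is deterministic and
idempotent; the legacy pre-2012 ISR dialect is out of scope.

Parsing is tolerant by design: lines whose field count disagrees with the
header are skipped and tallied, orphan DRUG/REAC/OUTC/THER rows (no
matching DEMO `primaryid`) are dropped and tallied, and all tallies
surface in the run manifest so silent data loss is visible. FAERS dates
are 4/6/8-digit strings and are kept at their native precision
(year/month/day) rather than coerced.

## Cohort construction

Reports enter the analysis set when (i) any drug mention's indication PT
matches, case-insensitively and whole-term, a breast-cancer term list
(30 terms, shipped as the default), and (ii) the drug role pattern
satisfies one of three rules over drug A (default search term
"pembrolizumab") and drug B ("paclitaxel"), matched case-insensitively
as substrings of the drug name or active-ingredient field (so
"KEYTRUDA (PEMBROLIZUMAB)" and "nab-paclitaxel" match):

* **A-only**: A as primary suspect (PS) and B absent in any role;
* **B-only**: symmetric;
* **combination**: A as PS with B in any role, or B as PS with A in any
  role.

These rules are mutually exclusive (verified by exhaustive enumeration
over all 25 role patterns). A report naming both drugs as PS is not
covered by the three rules as stated; it is assigned to the combination
group — both drugs are suspected and co-reported — and exercised
explicitly by the generator's "messy" mode. Indication matching is exact
on the lower-cased PT (not substring) to avoid composites like "breast
cancer screening" matching, and scans every drug mention's indication,
since restricting to the suspect drug is not clearly preferable and
would only shrink the analysis set.

Baseline tables count sex, weight bands (<50, 50–100, >100 kg), age
bands (18–64, 65–85) and outcome categories per group, with both the
pooled-cohort denominator (the convention of the published baseline
table, rows summing to 100% across groups) and per-group percentages,
labelled separately.

## Disproportionality statistics

For one event term and an index/comparator design the 2×2 table is
a (index with event), b (index without), c, d (comparator likewise);
each report counts once per term regardless of repeated PT mentions.
The estimators are:

* **ROR** = ad/bc with Woolf CI exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)),
  z = 1.96 by default (the conventional printed value; cross-checks
  against statsmodels' `Table2x2` use the exact normal quantile).
* **IC** (BCPNN with +0.5 shrinkage): with n₁₁ = a, E₁₁ = (a+b)(a+c)/N,
  IC = log₂((n₁₁+0.5)/(E₁₁+0.5)) and the closed-form lower bound
  IC025 = IC − 3.3(n₁₁+0.5)^−1/2 − 2(n₁₁+0.5)^−3/2. The shrinkage pulls
  small-count terms toward 0 (property-tested); an all-equal-cell table
  gives IC = 0 exactly.
* **Signal criterion**: ROR > 1 ∧ IC > 0 ∧ IC025 > 0, strict.

Zero cells make the ROR undefined; the library default is a hard error
naming the affected terms, with an optional Haldane–Anscombe +0.5
correction. The analysis drivers enable the correction because rare
immune events against a ~200-report comparator routinely produce c = 0;
the error default remains so that silent correction never happens in
library use. Screening keeps terms with a ≥ min_count (default 3, the
conventional pharmacovigilance noise floor), ranks by descending ROR
with ties broken by descending a then term. Both group-vs-group (the
default, matching the combination-vs-monotherapy design) and pooled
comparators are supported. SOC frequency tables are event-level (each
distinct PT of a report contributes one event to its SOC) with
percentages of the column total; PT→SOC mappings are supplied as a
two-column file — no dictionary content is bundled.

## Time-to-onset

Onset = event date − earliest therapy start among the report's drug
mentions (one onset per report). THER rows link to drug mentions by
sequence number when present, else the case's earliest start is used.
Strict mode (default) requires day precision on both dates; imputed mode
substitutes day 15 for month-precision and July 15 for year-precision
dates. Negative onsets are excluded; all exclusions are tallied.

Spontaneous reports are event-driven, so all records are treated as
observed events — the KM curve describes time-to-reported-event; a
censoring flag exists for synthetic studies. Quartiles use linear
interpolation (type 7), so IQR endpoints are reproducible; the KM median
is the smallest t with S(t) ≤ 0.5 and is reported as absent when the
curve never reaches 0.5 (the analogue of a printed "Inf" upper
quartile). Group comparisons per stratum (overall, top-3 SOCs by event
count) report median/IQR, the k-group log-rank test, and Cox
proportional-hazards ratios of each monotherapy against the combination
(single group indicator, Breslow tie handling via statsmodels `PHReg`,
Wald CI). Strata with fewer than `min_events` (default 5) records in any
present group are skipped and logged. Kaplan–Meier and log-rank
computations use lifelines; both are verified against hand-computed
product-limit and O−E/variance oracles in the tests.

## Synthetic data generator

The generator emulates the study conditions: group sizes 550/362/204
(combination/pembrolizumab/paclitaxel), quarters 2016q1–2023q2,
demographic and outcome-category probabilities taken from the published
baseline counts, exponential onset distributions with medians 35/43/42
days, duplicate-version rate 5%, partial-date rate 10%. A 15-PT catalog
spans 8 SOCs with background probabilities between 0.001 (hypophysitis,
myocarditis) and 0.20 (fatigue); the four immune-mediated events are
planted at elevated reporting odds in both pembrolizumab-containing
groups — at the published odds ratios 189.94 (adrenal insufficiency),
99.46 (hypophysitis), 69.5 (myocarditis), and 20 for immune-mediated
enterocolitis, for which no estimate is printed; backgrounds for these
rare events are not published and were set once at 0.001–0.002,
plausible FAERS report-level frequencies for rare immune toxicity.
Event presence is an independent Bernoulli draw per report and PT; an
injected signal tilts the background probability on the odds scale
(odds(p_index) = OR · odds(p_bg)), which makes the planted
report-level odds ratio exact by construction. One root seed spawns
independent per-stream generators (demographics, events, onsets, dates,
duplicates), so adding a stream never perturbs another and identical
seeds give byte-identical files.

What the generator does **not** emulate: secular reporting trends
(quarters are uniform, unlike the real rise after 2021), PT
co-occurrence structure, drug co-reporting networks, free-text drug-name
noise, multi-indication reports, or PT-specific onset distributions
(onsets are group-level). Passing tests therefore demonstrate that the
pipeline recovers planted structure under FAERS-like mechanics — not
that real-data estimates are unbiased, since real duplicate patterns and
reporting artefacts are richer.

## Numerical and validation choices

* ROR/CI agree with direct full-precision formula evaluation to
  < 1e-12 relative error over random tables with cells in [1, 10⁴].
* Parameter recovery: with planted OR ∈ {2, 5, 20} at n = 2000/group and
  background 0.05, the 95% CI covers the truth in ≥ 90% of 200
  replicates and the mean relative bias stays under 5%. These
  simulations drive the generator's event-sampling core directly; a
  file-level round trip at one seed separately confirms the planted OR
  survives serialize → parse → join → dedup → screen.
* Survival engine: log-rank size 0.05 ± 0.03 under an exponential null
  (500 replicates, n = 50/group); Cox log-HR bias < 0.05 at true
  HR 0.75, n = 2000/group, 200 replicates; KM median within 5% of the
  analytic median at n = 5000. The replicate counts and sample sizes are
  the package's validation conditions and keep the whole suite at a few
  minutes on one CPU.
* The published SOC frequency table reproduces from its printed counts
  to within ±0.01 percentage points — a handful of printed cells are
  truncated rather than rounded, which the tolerance absorbs.

## Known limitations

Only the `primaryid`/`caseid` dialect is read; dedup cannot emulate
FDA's full multi-criteria duplicate detection, so retained-report counts
on real archives will differ from any one published accounting. The Cox
model fits a single group indicator (no age/weight adjustment), matching
the comparative design; IC025 uses the closed-form approximation (a
Monte-Carlo credible interval is not implemented). SOC-level statistics
depend entirely on the user-supplied PT→SOC mapping.
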