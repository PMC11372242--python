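# faerspv

Comparative pharmacovigilance of **pembrolizumab + paclitaxel combination
therapy versus either monotherapy in breast cancer**, from FAERS-style
spontaneous adverse-event reports.

Spontaneous reporting systems such as the FDA Adverse Event Reporting
System (FAERS) publish quarterly `$`-delimited ASCII tables (DEMO, DRUG,
REAC, OUTC, THER) keyed by `primaryid` (report version) and `caseid`
(persistent case). This package implements, as a tested library plus
analysis drivers, the full comparative workflow over that dialect:

1. **Ingest** — parse and join the five tables, tolerate malformed lines
   (skip-and-tally), deduplicate case versions by keeping the largest
   `primaryid` per `caseid`.
2. **Cohorts** — keep reports whose drug indication matches a
   breast-cancer preferred-term list, then assign each by its drug role
   codes (PS primary suspect / SS / C / I): *combination* (one drug PS,
   the other in any role), *pembrolizumab-only* (PS, no paclitaxel),
   *paclitaxel-only* (symmetric).
3. **Disproportionality** — per event term, the 2×2 table
   (a = index-group reports with the event, b without; c, d likewise for
   the comparator) gives the reporting odds ratio

   ROR = ad/bc,  95% CI = exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)),

   and the BCPNN information component with shrinkage

   IC = log₂((n₁₁ + 0.5)/(E₁₁ + 0.5)),  E₁₁ = (a+b)(a+c)/N,
   IC025 = IC − 3.3(n₁₁+0.5)^−1/2 − 2(n₁₁+0.5)^−3/2.

   A term is a **safety signal** when ROR > 1 and IC > 0 and IC025 > 0.
4. **Time-to-onset** — onset = event date − earliest therapy start;
   groups compared by median/IQR, Kaplan–Meier curves, log-rank tests and
   Cox proportional-hazards ratios (Breslow ties).
5. **Synthetic generator** — emits multi-quarter bundles in the exact
   dialect the ingest consumes, with known ground truth (group sizes,
   planted per-PT odds ratios, parametric onset distributions, duplicate
   case versions), so every stage is testable without downloads.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
bundle generated at the study conditions (550 combination / 362
pembrolizumab / 204 paclitaxel breast-cancer reports over 2016q1–2023q2,
immune-mediated adverse events planted at elevated odds in the
pembrolizumab-containing groups, exponential onsets with medians 35/43/42
days):

```bash
python analysis/01_simulate.py
python analysis/02_cohort.py
python analysis/03_signals.py
python analysis/04_time_to_onset.py
```

Output from `03_signals.py` (combination vs paclitaxel-only):

```
vs_drug_b_only: 15 terms screened, 1 flagged
  adrenal insufficiency               ROR   156.52 (   9.70-  2526.74)  IC  0.45 IC025  0.19  signal=True
  hypophysitis                        ROR    39.48 (   2.42-   643.25)  IC  0.45 IC025 -0.03  signal=False
  myocarditis                         ROR    34.18 (   2.09-   558.13)  IC  0.45 IC025 -0.06  signal=False
```

The planted adrenal-insufficiency excess is recovered with the very wide
CI characteristic of a rare event against a 204-report comparator; the
screening table, forest-plot extract and SOC frequency table land in
`results/analysis/signals/`. From `04_time_to_onset.py`:

```
stratum: overall (log-rank p=0.0004426)
  combination    n= 447 median 35 days (IQR 15-67)
  drug_a_only    n= 299 median 45 days (IQR 21-83)
  drug_b_only    n= 168 median 43 days (IQR 17-90)
  HR drug_a_only vs combination: 0.763 (0.658-0.884), p=0.000332
  HR drug_b_only vs combination: 0.788 (0.659-0.942), p=0.00905
```

i.e. adverse events surface faster under combination therapy (35 vs 43/45
days; both monotherapy hazard ratios < 1), matching the planted onset
distributions. The same pipeline runs on real FAERS quarters: point
`faerspv report --input-dir <dir>` at a directory of
`DEMO2016q1.txt`-style files (plus a `pt$soc` mapping file) — see the CLI:

```bash
faerspv simulate --output-dir scratch/bundle --seed 17
faerspv report --input-dir scratch/bundle --output-dir results/run --seed 17
```

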