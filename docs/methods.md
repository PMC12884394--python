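# Methods

## Design

The package implements a *within-class* disproportionality screen on
spontaneous adverse-event reports. The background ("reference dataset") is not
the whole database but every deduplicated report in which one of ten
pre-specified antiseizure medications (carbamazepine, clonazepam, diazepam,
lamotrigine, levetiracetam, oxcarbazepine, phenobarbital, phenytoin,
topiramate, valproic acid and its salts) appears as the **primary suspect**
drug; cases are the reports in that background carrying the MedDRA Preferred
Term "Male infertility" (exact, case-insensitive match — no substring or
hierarchy matching). This restriction trades generalizability for
specificity: each drug is compared against reporting for the other drugs of
the same class, which dampens class-wide confounding but means a strong
signal for one drug *depresses* the apparent ratios of the others (visible in
the synthetic recovery tests, where null drugs fall below ROR 1).

A consequence worth stating: drug-level estimates from a within-class
background are not comparable with estimates computed against a whole-database
background, and published drug-level values cannot be reproduced without the
full multi-year extract. The package therefore treats published headline
numbers only as *inputs* to the criteria/formatting layers
(`faersig.example_screen`), and validates the statistics against closed-form
and simulation oracles instead.

## Ingestion and deduplication

Quarterly ASCII tables ("$"-delimited with a header) are parsed under a
quarantine-not-crash policy: a malformed line (bad date, non-numeric age,
unknown role code, empty PT) becomes a quarantine entry with a reason, and
typed rows + quarantine entries always equal the data-line count. Hard errors
are reserved for structural faults (a missing mandatory column). Empty
strings and `NA` are missing; dates must be `YYYYMMDD` within
[1900-01-01, today].

A FAERS case may be present as several report versions. Per CASEID the row
maximizing `(FDA_DT, PRIMARYID)` lexicographically is retained — latest
receipt date first, higher PRIMARYID on ties. Rows with missing FDA_DT are
ranked below any dated row for the same case: the rule presumes dates exist,
and discarding the information-poor version is the conservative resolution.
Deduplication is idempotent and order-invariant (the output is sorted by
CASEID). Only the modern PRIMARYID/CASEID schema is supported; legacy
ISR-keyed files predating it are out of scope.

Drug-name normalization is an explicit lexicon (packaged as an editable TSV):
case- and whitespace-insensitive exact lookup, active-ingredient field first,
verbatim name second, covering brands and salts (e.g. Tegretol →
carbamazepine, divalproex sodium → valproic acid). Unmapped names return
no-match; there is deliberately no fuzzy matching, since a silent mis-mapping
would contaminate the exposure margin.

Reports with two study drugs as co-primary suspects carry both labels: they
enter each drug's exposed margin but count once in the overall reference
total, so per-drug column totals need not sum to the reference size. In the
2×2 tables "other drugs" is the report-level complement (reports not labeled
with the target drug), keeping a+b+c+d equal to the reference size for every
drug.

## Summaries

Age is converted to years via the unit code (DEC ×10, YR, MON ÷12, WK ÷52.18,
DY ÷365.25, HR ÷8766; any other or missing code → unknown), weight to kg
(LBS ×0.453592). Bands are `<18, [18,65), [65,85], >85` years and
`<50, [50,100], >100` kg — the conventional report labels "18–64.9" and
"50–100" overlap at the boundary, so 65.0 goes up, and 85.0/100.0 are taken
inclusive in the middle band. Each report falls in exactly one band per
dimension, so band counts partition the per-drug totals (enforced by test).
Serious-outcome codes are multi-valued and counted once per listed code.
Percentages are computed against per-drug totals and rounded half-up only at
presentation (1 decimal; the overall case proportion at 2 decimals).

## Estimators and numerical choices

- **ROR**: `ad/bc` with the Woolf interval
  `exp(ln ROR ± z·√(1/a+1/b+1/c+1/d))`, z = 1.959964 (not 1.96; rounding only
  at presentation). When any cell is zero, the Haldane–Anscombe +0.5 is added
  to **all four** cells (standard pharmacovigilance practice; switchable).
- **PRR**: `[a/(a+b)]/[c/(c+d)]` on the same corrected cells; χ² is the
  Yates-corrected Pearson statistic `N(|ad−bc|−N/2)²/[(a+b)(c+d)(a+c)(b+d)]`,
  floored at zero, because the classic PRR ≥ 2 / χ² ≥ 4 / ≥3-cases criterion
  was defined with the correction. An empty event margin (a+c = 0) yields
  PRR = NaN (flag false), not a corrected pseudo-value.
- **BCPNN IC**: the shrinkage information component
  `log2((a+0.5)/(E+0.5))`, `E = (a+b)(a+c)/N`. The credibility bound is the
  genuinely open design point (spontaneous-report literature uses several
  variants), so both are provided and tested: the default Norén-style
  expansion `IC025 ≈ IC − 3.3(a+0.5)^{−1/2} − 2(a+0.5)^{−3/2}`, and an exact
  mode taking log2 of the 2.5th percentile of the Gamma(a+0.5, E+0.5)
  posterior for the observed/expected ratio. On moderate counts the two agree
  to ~0.1; the choice is surfaced in configuration and the run manifest.
- **MGPS/EBGM**: λ ~ `w·Gamma(α₁,β₁) + (1−w)·Gamma(α₂,β₂)` (shape/rate);
  marginally `a` is a two-component negative-binomial mixture, whose summed
  log-likelihood over all pairs is maximized with L-BFGS-B on log-scale
  parameters (logit for w) from the fixed starting point
  (0.2, 0.1, 2.0, 4.0, 1/3), bounds ±12 on the log scale — deterministic, no
  random restarts. Pairs with E = 0 are excluded from the fit and scored NaN.
  The posterior is the conjugate mixture `Q·Gamma(α₁+a, β₁+E) + (1−Q)·…`
  with Q from the component marginals; `EBGM = exp(E[ln λ])` via the digamma
  function, and EB05 by Brent root-finding on the mixture CDF (bracket from
  component quantiles, |f|-tolerance 1e-12). The "lower 95% confidence
  interval of EBGM" criterion is implemented as EB05 > 2, the standard MGPS
  reading; the threshold is configurable. Note that with only ten pairs (one
  screen) the five-hyperparameter fit is weakly identified — shrinkage is
  then aggressive; the fit is intended for, and validated on, thousands of
  pairs.

## Synthetic data: what it emulates, what it does not

The generator is a stated world, fixed up front. Defaults mirror the
reference screen this package re-implements: 81,618 reports over
2004-01-01..2024-09-30; per-drug exposure probabilities proportional to the
screen's per-drug report totals (two of the ten drugs contribute zero);
baseline target-PT probability 60/81,618; 70% missing weight and 30% missing
age; all-male sex (as the screen's demographic table reports); reporter,
outcome and country mixes matching its marginal percentages; 10% injected
near-duplicates. Drugs are drawn independently per report; one drawn drug is
flagged PS uniformly at random, the others SS/C; reports drawing no study
drug receive a non-study filler PS (and are correctly excluded by the cohort
stage). The target-PT probability is `min(1, baseline·rr_PS)` keyed on the PS
drug only, mirroring the exposure definition, so the injected ratio is
interpretable under the pipeline's own cohort rule. Duplicates alternate
between a +30-day FDA_DT (exercising the recency clause) and an identical
date with a higher PRIMARYID (exercising the tie clause). About 30% of study
mentions use a brand synonym with an empty ingredient field, forcing the
cohort stage through the lexicon.

`expected_tables` enumerates the ≤2¹⁰ drug subsets to give exact expected
2×2 cells — the analytic oracle for recovery tests.

Not modelled: correlation between drugs and demographics, temporal reporting
trends, polytherapy role structure beyond one PS per report, misspelled drug
names, and real FAERS quirks (country free-text variants, partial dates). A
green recovery test therefore establishes that the pipeline's statistics are
correct and calibrated *under independent-draw reporting*, not that real
FAERS counts would be reproduced.

Two worlds used by the statistical acceptance tests are fixed a priori where
the defaults would be too sparse: CI calibration uses a three-drug extract at
n = 20,000 with a 1% target-PT rate (≈40 exposed cases per replicate, the
asymptotic regime of the Woolf interval); the MGPS sanity check uses 4,000
null pairs with E log-uniform on [0.5, 200].

## Pipeline

`run()` executes parse → dedup → join → reference set → cases → summaries →
contingencies → statistics → criteria → outputs, logging stage counts in
funnel order (raw rows ≥ deduplicated ≥ reference ≥ cases). The YAML manifest
(resolved configuration, package version, stage counts) is written even when
a stage fails, with the failing stage named. Forest ordering is ROR
descending with alphabetical tie-break and a null line at ROR = 1.

## Known limitations

- Single-PT exact matching only; no MedDRA hierarchy (SOC/HLT/SMQ).
- No exposure-duration (THER) or indication (INDI) modelling.
- The within-class background makes cross-class comparisons invalid by
  construction.
- Statistics on very small case counts (a ≤ 3) are dominated by the
  continuity/shrinkage choices; the criteria handle this (the ≥3-case PRR
  clause, IC penalty terms), but point estimates should not be
  over-interpreted.
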