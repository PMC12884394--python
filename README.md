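# faersig

Disproportionality signal detection for FAERS-style spontaneous adverse-event
reports, built around a concrete pharmacovigilance question: do antiseizure
medications (ASMs) show disproportionate reporting of **male infertility**?

Spontaneous-report databases such as the FDA Adverse Event Reporting System
(FAERS) have no exposure denominators, so drug–event associations are screened
by *disproportionality*: for each drug–event pair a 2×2 table is formed
against a background of reports,

|                | target event | other events |
|----------------|--------------|--------------|
| target drug    | a            | b            |
| other drugs    | c            | d            |

and reporting imbalance is quantified by four standard estimators:

- **ROR** (reporting odds ratio) `= ad/bc`, Woolf 95% CI
  `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`, Haldane–Anscombe +0.5 correction
  when a cell is zero;
- **PRR** `= [a/(a+b)]/[c/(c+d)]` with the Yates-corrected Pearson χ²;
- **BCPNN information component** `IC = log2((a+0.5)/(E+0.5))` with
  `E = (a+b)(a+c)/N`, lower bound IC025 by the Norén approximation or exact
  gamma-posterior quantile inversion;
- **EBGM** (DuMouchel's multi-item gamma-Poisson shrinker): `a ~ Poisson(λE)`
  with a two-component gamma-mixture prior on λ fitted by marginal
  (negative-binomial) maximum likelihood across all pairs; EBGM is the
  posterior geometric mean of λ and EB05 its 5th percentile.

Positive-signal criteria (configurable): ROR 95% lower bound > 1 **and**
IC025 > 0 (joint primary criterion); PRR ≥ 2 with χ² ≥ 4 and ≥ 3 cases;
EB05 > 2.

The package covers the whole path a screen needs:

- `faersig.io` — "$"-delimited DEMO/DRUG/REAC parsing with per-line
  quarantine accounting, the FAERS case-version deduplication rule (latest
  FDA_DT per CASEID, ties to the higher PRIMARYID), mention joining;
- `faersig.cohort` — canonical-drug normalization through an explicit
  brand/salt lexicon for the ten study ASMs, primary-suspect reference-set
  construction, case selection by exact MedDRA Preferred-Term match, and the
  usual descriptive tables (age/weight bands, reporter, outcomes, top-5
  countries, annual trend);
- `faersig.dispro` — the four estimators and criteria above;
- `faersig.synth` — a seeded generator of FAERS-like extracts with known
  ground truth (per-drug exposure probabilities, injected relative reporting
  ratios, duplicates, realistic missingness) plus exact expected 2×2 cells by
  enumeration, so calibration and recovery are testable offline;
- `faersig.pipeline` / `faersig.cli` — one-command orchestration producing a
  CSV bundle, a forest-plot table ordered by ROR, optional plots, and a YAML
  manifest that makes every number reproducible.

## Worked example

Simulate a 20,000-report extract with an 8-fold reporting-ratio spike on
carbamazepine, then screen it:

```python
from faersig import (SynthConfig, generate, deduplicate, join_reports,
                     build_reference_set, CohortSpec, DrugLexicon, signal_screen)

cfg = SynthConfig(n_reports=20000, baseline_pt_prob=0.005,
                  rr_map={"carbamazepine": 8.0}, seed=1)
tables = generate(cfg)
demo = deduplicate(tables.demo)                      # 22,000 raw -> 20,000
joined = join_reports(demo, tables.drug, tables.reac)
ref = build_reference_set(joined, CohortSpec(), DrugLexicon.default())
out = signal_screen(ref, "Male infertility")
print(out[["drug", "a", "ror", "ror_lo95", "ic", "ic025", "ror_bcpnn_positive"]])
```

```
            drug   a       ror  ror_lo95        ic     ic025  ror_bcpnn_positive
0  carbamazepine  70  8.474702  5.941614  2.034409  1.638006                True
1     clonazepam   6  0.577762  0.253866 -0.691482 -2.106535               False
2    lamotrigine  13  0.571858  0.321515 -0.673085 -1.611552               False
...
```

The spiked drug is recovered (ROR ≈ 8.5 against a true ratio of 8, lower CI
bound 5.9 > 1, IC025 1.6 > 0), and every null drug stays below both
thresholds — their RORs sit *below* 1 because in a within-class screen the
spiked drug inflates the shared background event rate.

The same screen from the shell:

```bash
faersig simulate raw/ --n-reports 20000 --seed 1
faersig run run.yaml        # points input_dir at raw/, output_dir at out/
faersig report out/
```

## Acceptance script

`scripts/acceptance.py` regenerates a seeded synthetic extract whose exposure
mix and per-drug reporting-ratio ordering mirror the published ten-drug ASM
screen (at half volume), writes it to ASCII, ingests it back through the
parser, and runs the complete pipeline — deduplication, cohort, summaries,
all four statistics and the signal criteria — printing the stage counts and
flagged drugs:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
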