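"""Seeded generator of FAERS-like DEMO/DRUG/REAC tables with known ground truth.

The generator emulates the structure of a spontaneous-reporting extract for a
ten-drug antiseizure study set: per-report drug mentions drawn independently
per drug with exactly one flagged primary suspect (PS), a target MedDRA
Preferred Term whose reporting probability is multiplied by a per-drug
relative reporting ratio when that drug is the PS, filler background PTs,
demographics with realistic missingness (defaults: 70% unknown weight, 30%
unknown age), categorical reporter/outcome/country fields, uniform FDA
receipt dates over the study window, and injected near-duplicate report
versions (same CASEID, later FDA_DT and/or higher PRIMARYID) to exercise the
deduplication rule.

Default exposure probabilities are proportional to the per-drug report totals
of the reference screen this package re-implements (81,618 reports over
2004-01-01..2024-09-30, two of the ten drugs contributing none), and the
default baseline target-PT probability is its overall case proportion
(60/81,618).  Generation is a pure function of the configuration, including
its seed.

``expected_tables`` computes the exact expected 2×2 cells per drug by
enumerating drug subsets, giving tests an analytic oracle for parameter
recovery.
"""

from __future__ import annotations

import datetime
import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from faersig import io as fio
from faersig.cohort import STUDY_ASMS, DrugLexicon

__all__ = ["SynthConfig", "SynthTables", "generate", "expected_tables", "write_tables"]

#: per-drug report totals of the reference screen (drugs absent → 0)
_SCREEN_DRUG_TOTALS: dict[str, int] = {
    "carbamazepine": 11178,
    "clonazepam": 7063,
    "diazepam": 0,
    "lamotrigine": 13817,
    "levetiracetam": 19388,
    "oxcarbazepine": 3648,
    "phenobarbital": 0,
    "phenytoin": 7047,
    "topiramate": 5193,
    "valproic acid": 14284,
}
_SCREEN_TOTAL = 81618
_SCREEN_CASES = 60

_DEFAULT_DRUG_PROBS = {
    d: n / _SCREEN_TOTAL for d, n in _SCREEN_DRUG_TOTALS.items()
}

_DEFAULT_BACKGROUND_PTS: tuple[tuple[str, float], ...] = (
    ("Seizure", 0.12),
    ("Drug ineffective", 0.10),
    ("Nausea", 0.08),
    ("Dizziness", 0.06),
    ("Somnolence", 0.05),
    ("Headache", 0.05),
    ("Rash", 0.04),
    ("Fatigue", 0.04),
)

_DEFAULT_REPORTER_WEIGHTS = {
    "CN": 0.33, "HP": 0.11, "LW": 0.01, "MD": 0.23, "OT": 0.16,
    "PH": 0.09, "RN": 0.01, "": 0.06,
}
_DEFAULT_OUTCOME_WEIGHTS = {
    "CA": 0.02, "DE": 0.07, "DS": 0.02, "LT": 0.27, "HO": 0.05,
    "OT": 0.36, "RI": 0.01, "": 0.20,
}
_DEFAULT_COUNTRY_WEIGHTS = {
    "US": 0.42, "FR": 0.08, "GB": 0.07, "JP": 0.06, "DE": 0.05,
    "CN": 0.04, "CA": 0.03, "IT": 0.03, "BR": 0.03, "IN": 0.02,
    "OTHER": 0.17,
}

#: non-study filler drug given to reports that drew no study drug
_FILLER_DRUG = "IBUPROFEN"


@dataclass(frozen=True)
class SynthConfig:
    """Stated world for one synthetic FAERS extract.

    ``drug_probs`` are independent per-report exposure probabilities (they
    need not sum to 1; a report may draw several drugs, and one of the drawn
    drugs is flagged PS uniformly at random).  ``rr_map`` multiplies the
    baseline target-PT probability when the keyed drug is the PS (drugs not
    listed have ratio 1).  ``dup_rate`` is the fraction of reports re-emitted
    as near-duplicate versions.
    """

    n_reports: int = 81618
    drug_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DRUG_PROBS))
    baseline_pt_prob: float = _SCREEN_CASES / _SCREEN_TOTAL
    rr_map: Mapping[str, float] = field(default_factory=dict)
    target_pt: str = "Male infertility"
    background_pts: Sequence[tuple[str, float]] = _DEFAULT_BACKGROUND_PTS
    dup_rate: float = 0.1
    missing_age_frac: float = 0.3
    missing_weight_frac: float = 0.7
    sex_weights: Mapping[str, float] = field(
        default_factory=lambda: {"M": 1.0})
    reporter_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_REPORTER_WEIGHTS))
    outcome_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_OUTCOME_WEIGHTS))
    country_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COUNTRY_WEIGHTS))
    date_range: tuple[datetime.date, datetime.date] = (
        datetime.date(2004, 1, 1),
        datetime.date(2024, 9, 30),
    )
    brand_name_frac: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        for d, p in self.drug_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"drug_probs[{d!r}]={p} outside [0,1]")
        if not 0 <= self.baseline_pt_prob <= 1:
            raise ValueError("baseline_pt_prob outside [0,1]")
        for d, rr in self.rr_map.items():
            if rr <= 0:
                raise ValueError(f"rr_map[{d!r}] must be > 0")
            if self.baseline_pt_prob * rr > 1:
                raise ValueError(
                    f"target-PT probability exceeds 1 for drug {d!r}: "
                    "reduce baseline_pt_prob or rr"
                )
        if not 0 <= self.dup_rate <= 0.5:
            raise ValueError("dup_rate must lie in [0, 0.5]")
        for name, frac in (("missing_age_frac", self.missing_age_frac),
                           ("missing_weight_frac", self.missing_weight_frac),
                           ("brand_name_frac", self.brand_name_frac)):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} outside [0,1]")
        for name, w in (("sex_weights", self.sex_weights),
                        ("reporter_weights", self.reporter_weights),
                        ("outcome_weights", self.outcome_weights),
                        ("country_weights", self.country_weights)):
            if not w or any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
                raise ValueError(f"{name} must be nonnegative with positive sum")
        for pt, p in self.background_pts:
            if not 0 <= p <= 1:
                raise ValueError(f"background PT {pt!r} probability outside [0,1]")
        if self.date_range[0] > self.date_range[1]:
            raise ValueError("date_range start must be <= end")

    def pt_prob(self, drug: str | None) -> float:
        """Target-PT probability for a report whose PS drug is ``drug``."""
        rr = self.rr_map.get(drug, 1.0) if drug is not None else 1.0
        return min(1.0, self.baseline_pt_prob * rr)


@dataclass
class SynthTables:
    """Generated tables plus the per-report ground truth used by tests."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    #: ground truth, one row per original (pre-duplicate) report:
    #: caseid, ps_drug (canonical or filler), has_target_pt
    truth: pd.DataFrame


def _draw_categorical(rng: np.random.Generator, weights: Mapping[str, float],
                      n: int) -> np.ndarray:
    keys = np.array(list(weights.keys()), dtype=object)
    p = np.array(list(weights.values()), dtype=float)
    p = p / p.sum()
    return rng.choice(keys, size=n, p=p)


def generate(config: SynthConfig) -> SynthTables:
    """Generate one synthetic extract; deterministic given the config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    drugs = list(config.drug_probs.keys())
    probs = np.array([config.drug_probs[d] for d in drugs], dtype=float)
    ndrug = len(drugs)

    # exposure matrix and uniform PS choice among drawn drugs
    exposed = rng.random((n, ndrug)) < probs[None, :]
    tie = rng.random((n, ndrug))
    score = np.where(exposed, tie, -1.0)
    ps_idx = score.argmax(axis=1)
    any_drug = exposed.any(axis=1)
    ps_drug = np.array(
        [drugs[i] if ok else _FILLER_DRUG for i, ok in zip(ps_idx, any_drug)],
        dtype=object,
    )

    # target-PT indicator keyed on the PS drug's relative reporting ratio
    pt_prob = np.full(n, config.baseline_pt_prob)
    for d, rr in config.rr_map.items():
        pt_prob[ps_drug == d] = config.pt_prob(d)
    has_pt = rng.random(n) < pt_prob

    caseid = np.arange(1, n + 1, dtype=np.int64)
    primaryid = caseid * 10 + 1

    start, end = config.date_range
    span = (end - start).days
    day_offsets = rng.integers(0, span + 1, size=n)
    fda_dt = pd.to_datetime(start) + pd.to_timedelta(day_offsets, unit="D")

    age = np.clip(rng.normal(45.0, 20.0, size=n), 0.5, 95.0).round(1)
    age_missing = rng.random(n) < config.missing_age_frac
    wt = np.clip(rng.normal(75.0, 18.0, size=n), 30.0, 160.0).round(1)
    wt_missing = rng.random(n) < config.missing_weight_frac

    sex = _draw_categorical(rng, config.sex_weights, n)
    reporter = _draw_categorical(rng, config.reporter_weights, n)
    outcome = _draw_categorical(rng, config.outcome_weights, n)
    country = _draw_categorical(rng, config.country_weights, n)

    demo = pd.DataFrame({
        "primaryid": primaryid,
        "caseid": caseid,
        "fda_dt": fda_dt,
        "age": np.where(age_missing, np.nan, age),
        "age_cod": np.where(age_missing, "", "YR"),
        "sex": sex.astype(str),
        "wt": np.where(wt_missing, np.nan, wt),
        "wt_cod": np.where(wt_missing, "", "KG"),
        "occp_cod": reporter.astype(str),
        "country": country.astype(str),
        "outc_cod": outcome.astype(str),
    })

    # drug mentions: the PS mention plus SS/C mentions for other drawn drugs
    lexicon = DrugLexicon.default()
    brand_pick = rng.random(n) < config.brand_name_frac
    brand_idx = rng.integers(0, 10**9, size=n)

    rows, cols = np.nonzero(exposed)
    generic = np.array([d.upper() for d in drugs], dtype=object)
    name_arr = generic[cols].copy()
    ai_arr = generic[cols].copy()
    for j, d in enumerate(drugs):
        brands = [s.upper() for s in lexicon.synonyms_of(d) if s != d]
        if not brands:
            continue
        sel = brand_pick[rows] & (cols == j)
        if sel.any():
            idx = brand_idx[rows[sel]] % len(brands)
            name_arr[sel] = np.array(brands, dtype=object)[idx]
            # brand-name mentions come without an ingredient field, so the
            # cohort layer has to resolve them through the synonym lexicon
            ai_arr[sel] = ""
    other = rng.choice(np.array(["SS", "C"], dtype=object), size=len(rows))
    role_arr = np.where(cols == ps_idx[rows], "PS", other)
    mention_pid = primaryid[rows]

    # filler mention for reports with no study drug (keeps them out of the cohort)
    filler_rows = np.nonzero(~any_drug)[0]
    drug_tbl = pd.DataFrame({
        "primaryid": np.concatenate([mention_pid, primaryid[filler_rows]]),
        "drugname": np.concatenate(
            [name_arr, np.full(len(filler_rows), _FILLER_DRUG, dtype=object)]),
        "prod_ai": np.concatenate(
            [ai_arr, np.full(len(filler_rows), _FILLER_DRUG, dtype=object)]),
        "role_cod": np.concatenate(
            [role_arr, np.full(len(filler_rows), "PS", dtype=object)]),
    }).sort_values("primaryid", kind="mergesort").reset_index(drop=True)
    drug_tbl["primaryid"] = drug_tbl["primaryid"].astype(np.int64)

    # events: target PT plus independent background PTs
    reac_pid: list[np.ndarray] = []
    reac_pt: list[np.ndarray] = []
    if has_pt.any():
        reac_pid.append(primaryid[has_pt])
        reac_pt.append(np.full(int(has_pt.sum()), config.target_pt, dtype=object))
    for pt, p in config.background_pts:
        mask = rng.random(n) < p
        reac_pid.append(primaryid[mask])
        reac_pt.append(np.full(int(mask.sum()), pt, dtype=object))
    if reac_pid:
        reac = pd.DataFrame({
            "primaryid": np.concatenate(reac_pid).astype(np.int64),
            "pt": np.concatenate(reac_pt),
        }).sort_values(["primaryid", "pt"], kind="mergesort").reset_index(drop=True)
    else:
        reac = pd.DataFrame({"primaryid": pd.Series(dtype=np.int64),
                             "pt": pd.Series(dtype=str)})
    reac["pt"] = reac["pt"].astype(str)

    # near-duplicate report versions: even picks get FDA_DT+30d (recency
    # clause), odd picks keep the date (tie broken by higher PRIMARYID)
    k = int(round(config.dup_rate * n))
    if k > 0:
        pick = np.sort(rng.choice(n, size=k, replace=False))
        dup = demo.iloc[pick].copy()
        bump = (np.arange(k) % 2) == 0
        dup["fda_dt"] = dup["fda_dt"] + pd.to_timedelta(np.where(bump, 30, 0), "D")
        dup["primaryid"] = dup["caseid"] * 10 + 2
        demo_out = pd.concat([demo, dup], ignore_index=True)
        dup_pids = set(demo["primaryid"].iloc[pick])
        for tbl_name in ("drug_tbl", "reac"):
            tbl = locals()[tbl_name]
            extra = tbl[tbl["primaryid"].isin(dup_pids)].copy()
            extra["primaryid"] = (extra["primaryid"] // 10) * 10 + 2
            if tbl_name == "drug_tbl":
                drug_tbl = pd.concat([drug_tbl, extra], ignore_index=True)
            else:
                reac = pd.concat([reac, extra], ignore_index=True)
    else:
        demo_out = demo

    truth = pd.DataFrame({
        "caseid": caseid,
        "ps_drug": ps_drug,
        "has_target_pt": has_pt,
    })
    return SynthTables(demo=demo_out, drug=drug_tbl, reac=reac, truth=truth)


def write_tables(tables: SynthTables, directory: str | Path,
                 delimiter: str = "$") -> dict[str, Path]:
    """Write DEMO/DRUG/REAC as "$"-delimited text files; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind, frame in (("DEMO", tables.demo), ("DRUG", tables.drug),
                        ("REAC", tables.reac)):
        path = directory / f"{kind}.txt"
        fio.write_table(frame, kind, path, delimiter=delimiter)
        paths[kind] = path
    return paths


@dataclass(frozen=True)
class ExpectedTable:
    """Analytic expected 2×2 cells for one drug under the configured world."""

    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        return (self.a * self.d) / (self.b * self.c)


def expected_tables(config: SynthConfig) -> dict[str, ExpectedTable]:
    """Exact expected 2×2 cells per drug by enumeration over drug subsets.

    For each subset S of study drugs (drawn with probability
    ∏_{i∈S} p_i · ∏_{j∉S} (1−p_j)), the PS is uniform over S and the report
    enters the reference iff S is non-empty.  The target-PT probability
    depends only on the PS drug, so per-drug expected cells follow in closed
    form.  Cells are per the pipeline's own cohort rule: "exposed" means the
    report's PS drug is the target drug (PS-only role filter, single PS per
    report).
    """
    config.validate()
    drugs = [d for d in config.drug_probs]
    p = {d: config.drug_probs[d] for d in drugs}
    if len(drugs) > 16:
        raise ValueError("subset enumeration limited to 16 drugs")

    # P(PS = d): sum over subsets containing d of q_S / |S|
    ps_prob = {d: 0.0 for d in drugs}
    nonempty_prob = 0.0
    for r in range(1, len(drugs) + 1):
        for subset in itertools.combinations(drugs, r):
            q = 1.0
            inset = set(subset)
            for d in drugs:
                q *= p[d] if d in inset else (1.0 - p[d])
            if q == 0.0:
                continue
            nonempty_prob += q
            for d in subset:
                ps_prob[d] += q / r

    n = config.n_reports
    out = {}
    total_cases = sum(ps_prob[d] * config.pt_prob(d) for d in drugs)
    for d in drugs:
        a = n * ps_prob[d] * config.pt_prob(d)
        b = n * ps_prob[d] * (1.0 - config.pt_prob(d))
        c = n * (total_cases - ps_prob[d] * config.pt_prob(d))
        dd = n * (nonempty_prob - ps_prob[d]) - c
        out[d] = ExpectedTable(a=a, b=b, c=c, d=dd)
    return out
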