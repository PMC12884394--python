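"""Cohort construction and descriptive summaries for an ASM reference dataset.

The analysis design is a *within-class* disproportionality screen: the
background ("reference dataset") is every deduplicated report in which one of
ten pre-specified antiseizure medications (ASMs) is the primary-suspect (PS)
drug, and the cases are the reports in that background whose event list
contains the target MedDRA Preferred Term (here "Male infertility").  Drug
names are mapped to canonical ingredients through an explicit synonym lexicon
covering brand names and salts — exact, case-insensitive matching only, no
fuzzy guessing.

Descriptive outputs mirror the usual pharmacovigilance report: per-drug counts
by age band, weight band, reporter occupation, serious-outcome code, top-k
reporting countries, and annual report counts.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from faersig.io import JoinedReports

__all__ = [
    "STUDY_ASMS",
    "DrugLexicon",
    "CohortSpec",
    "DescriptiveSummary",
    "normalize_drug",
    "build_reference_set",
    "select_cases",
    "summarize",
    "annual_trend",
]

#: the ten-drug antiseizure study set
STUDY_ASMS: tuple[str, ...] = (
    "carbamazepine",
    "clonazepam",
    "diazepam",
    "lamotrigine",
    "levetiracetam",
    "oxcarbazepine",
    "phenobarbital",
    "phenytoin",
    "topiramate",
    "valproic acid",
)

#: age-unit code → factor converting the stored value to years
AGE_UNIT_TO_YEARS: Mapping[str, float] = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

AGE_BIN_LABELS = ("<18", "18-64.9", "65-85", ">85", "unknown")
WEIGHT_BIN_LABELS = ("<50", "50-100", ">100", "unknown")


def _norm_key(s: str) -> str:
    return " ".join(s.split()).lower()


class DrugLexicon:
    """Case-insensitive synonym → canonical-ingredient map for the study drugs.

    Every synonym maps to exactly one canonical name (checked at load time);
    looking up an unmapped string returns ``None``, never a guess.
    """

    def __init__(self, synonym_map: Mapping[str, str]):
        self._map: dict[str, str] = {}
        for raw, canonical in synonym_map.items():
            key = _norm_key(raw)
            canon = _norm_key(canonical)
            if key in self._map and self._map[key] != canon:
                raise ValueError(
                    f"lexicon conflict: {raw!r} maps to both "
                    f"{self._map[key]!r} and {canon!r}"
                )
            self._map[key] = canon
        # canonical names always resolve to themselves
        for canon in set(self._map.values()):
            self._map.setdefault(canon, canon)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DrugLexicon":
        """Load a two-column (synonym, canonical) tab-separated file."""
        frame = pd.read_csv(path, sep="\t", dtype=str)
        if not {"synonym", "canonical"} <= set(frame.columns):
            raise ValueError("lexicon file needs 'synonym' and 'canonical' columns")
        return cls(dict(zip(frame["synonym"], frame["canonical"])))

    @classmethod
    def default(cls) -> "DrugLexicon":
        """The packaged lexicon for the ten study ASMs (brands and salts)."""
        ref = resources.files("faersig").joinpath("data/asm_lexicon.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    @property
    def canonical_names(self) -> tuple[str, ...]:
        return tuple(sorted(set(self._map.values())))

    def lookup(self, raw: str | None) -> str | None:
        if raw is None:
            return None
        return self._map.get(_norm_key(raw))

    def synonyms_of(self, canonical: str) -> tuple[str, ...]:
        canon = _norm_key(canonical)
        return tuple(sorted(k for k, v in self._map.items() if v == canon))


def normalize_drug(
    raw_name: str | None,
    raw_ingredient: str | None,
    lexicon: DrugLexicon,
) -> str | None:
    """Map a verbatim drug mention to a canonical ingredient, or ``None``.

    The active-ingredient field is tried first (it is the cleaner FAERS field),
    then the verbatim drug name.  Matching is exact after case folding and
    whitespace normalization.
    """
    hit = lexicon.lookup(raw_ingredient) if raw_ingredient else None
    if hit is None:
        hit = lexicon.lookup(raw_name)
    return hit


@dataclass(frozen=True)
class CohortSpec:
    """Exposure and case definition for one screen.

    ``role_filter`` controls which FAERS role codes count as exposure
    (default: primary suspect only); ``date_window`` bounds FDA receipt dates
    (inclusive); ``restrict_sex`` optionally keeps only one sex code.
    """

    target_pt: str = "Male infertility"
    role_filter: tuple[str, ...] = ("PS",)
    date_window: tuple[datetime.date, datetime.date] = (
        datetime.date(2004, 1, 1),
        datetime.date(2024, 9, 30),
    )
    restrict_sex: str | None = None

    def __post_init__(self):
        if not self.target_pt.strip():
            raise ValueError("target_pt must be non-empty")
        if self.date_window[0] > self.date_window[1]:
            raise ValueError("date_window start must be <= end")
        if not self.role_filter:
            raise ValueError("role_filter must name at least one role code")


def build_reference_set(
    joined: JoinedReports,
    spec: CohortSpec,
    lexicon: DrugLexicon,
) -> pd.DataFrame:
    """Build the labeled reference dataset for disproportionality analysis.

    A report enters iff at least one drug mention with a role in
    ``spec.role_filter`` maps to a canonical study drug and its FDA date lies
    in the window.  The returned frame has one row per report: the DEMO
    columns plus ``asms`` (sorted tuple of matched canonical drugs — a report
    may match more than one) and ``pts`` (tuple of its event Preferred Terms).

    Raises ``ValueError`` on an empty result: downstream 2×2 statistics are
    undefined without a background.
    """
    demo, drug, reac = joined.demo, joined.drug, joined.reac

    exposed = drug[drug["role_cod"].isin(spec.role_filter)]
    # normalize each distinct (name, ingredient) pair once, then broadcast
    pairs = exposed[["drugname", "prod_ai"]].drop_duplicates()
    mapping = {
        (n, i): normalize_drug(n, i, lexicon)
        for n, i in zip(pairs["drugname"], pairs["prod_ai"])
    }
    canon = [
        mapping[(n, i)] for n, i in zip(exposed["drugname"], exposed["prod_ai"])
    ]
    exposed = exposed.assign(canonical=canon)
    exposed = exposed[exposed["canonical"].notna()]

    labels = (
        exposed.groupby("primaryid")["canonical"]
        .agg(lambda s: tuple(sorted(set(s))))
        .rename("asms")
    )

    pts = reac.groupby("primaryid")["pt"].agg(tuple).rename("pts")

    ref = demo.join(labels, on="primaryid").join(pts, on="primaryid")
    ref = ref[ref["asms"].notna()]

    start, end = (pd.Timestamp(d) for d in spec.date_window)
    ref = ref[(ref["fda_dt"] >= start) & (ref["fda_dt"] <= end)]
    if spec.restrict_sex is not None:
        ref = ref[ref["sex"] == spec.restrict_sex]

    ref = ref.copy()
    ref["pts"] = ref["pts"].apply(lambda v: v if isinstance(v, tuple) else ())
    ref = ref.reset_index(drop=True)
    if ref.empty:
        raise ValueError("empty reference set: no report matches the cohort spec")
    return ref


def case_mask(reference: pd.DataFrame, target_pt: str) -> pd.Series:
    """Boolean mask: report carries the target PT (case-insensitive exact match)."""
    key = _norm_key(target_pt)
    return reference["pts"].apply(
        lambda pts: any(_norm_key(p) == key for p in pts)
    )


def select_cases(reference: pd.DataFrame, target_pt: str) -> pd.DataFrame:
    """Subset of the reference whose event list contains ``target_pt``.

    Matching is exact on the whole Preferred Term after case folding —
    "Infertility" does not match "Male infertility".  An empty result is
    valid (zero reported cases).
    """
    return reference[case_mask(reference, target_pt)].reset_index(drop=True)


def age_in_years(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    """Convert (value, unit-code) age pairs to years; unconvertible → NaN."""
    factor = age_cod.str.upper().map(AGE_UNIT_TO_YEARS)
    return age * factor


def _bin_age_years(years: pd.Series) -> pd.Series:
    out = pd.Series("unknown", index=years.index, dtype="object")
    y = years.to_numpy(dtype="float64")
    with np.errstate(invalid="ignore"):
        out[(y >= 0) & (y < 18)] = "<18"
        out[(y >= 18) & (y < 65)] = "18-64.9"
        out[(y >= 65) & (y <= 85)] = "65-85"
        out[y > 85] = ">85"
    return out


def _bin_weight_kg(kg: pd.Series) -> pd.Series:
    out = pd.Series("unknown", index=kg.index, dtype="object")
    w = kg.to_numpy(dtype="float64")
    with np.errstate(invalid="ignore"):
        out[(w >= 0) & (w < 50)] = "<50"
        out[(w >= 50) & (w <= 100)] = "50-100"
        out[w > 100] = ">100"
    return out


def weight_in_kg(wt: pd.Series, wt_cod: pd.Series) -> pd.Series:
    """Convert weight to kilograms; KG/KGS pass through, LBS ×0.453592."""
    code = wt_cod.str.upper()
    factor = pd.Series(np.nan, index=wt.index)
    factor[code.isin(["KG", "KGS", ""])] = 1.0
    factor[code.isin(["LBS", "LB"])] = 0.453592
    return wt * factor


@dataclass
class DescriptiveSummary:
    """Per-drug descriptive tables for the reference dataset.

    ``age``, ``weight``, ``reporter`` and ``outcome`` are count frames with
    one column per drug plus ``all`` (report-level, so multi-drug reports are
    counted once); ``countries`` is a long frame of top-k countries per drug
    with percentages; ``totals`` maps each drug to its report count.
    """

    age: pd.DataFrame
    weight: pd.DataFrame
    reporter: pd.DataFrame
    outcome: pd.DataFrame
    countries: pd.DataFrame
    totals: pd.Series


def _drug_indicator(reference: pd.DataFrame, drugs: Sequence[str]) -> pd.DataFrame:
    cols = {d: reference["asms"].apply(lambda t, d=d: d in t) for d in drugs}
    cols["all"] = pd.Series(True, index=reference.index)
    return pd.DataFrame(cols)


def _crosstab(labels: pd.Series, indic: pd.DataFrame,
              row_order: Iterable[str]) -> pd.DataFrame:
    rows = {}
    for lab in row_order:
        mask = labels == lab
        rows[lab] = {col: int(indic.loc[mask, col].sum()) for col in indic.columns}
    return pd.DataFrame.from_dict(rows, orient="index", columns=indic.columns)


def summarize(
    reference: pd.DataFrame,
    drugs: Sequence[str] | None = None,
    top_k_countries: int = 5,
) -> DescriptiveSummary:
    """Demographic / reporting summary of the reference dataset.

    Age bands: <18, 18–64.9, 65–85 (85.0 inclusive), >85, unknown; weight
    bands: <50, 50–100 (100.0 inclusive), >100 kg, unknown.  Every report
    falls in exactly one band per dimension, so per-drug band counts sum to
    that drug's report total.
    """
    if drugs is None:
        drugs = sorted({d for t in reference["asms"] for d in t})
    indic = _drug_indicator(reference, drugs)
    totals = indic.sum().astype("int64")

    age_band = _bin_age_years(age_in_years(reference["age"], reference["age_cod"]))
    weight_band = _bin_weight_kg(weight_in_kg(reference["wt"], reference["wt_cod"]))

    reporter = reference["occp_cod"].replace("", "unknown")
    reporter_order = ["CN", "HP", "LW", "MD", "OT", "PH", "RN", "unknown"]
    reporter = reporter.where(reporter.isin(reporter_order), "unknown")

    # outcome is multi-valued; count a report once per listed code
    outcome_order = ["CA", "DE", "DS", "LT", "HO", "OT", "RI", "unknown"]
    outc_rows = {}
    listed = reference["outc_cod"].str.split(",")
    for code in outcome_order[:-1]:
        mask = listed.apply(lambda cs, c=code: c in cs)
        outc_rows[code] = {col: int(indic.loc[mask, col].sum()) for col in indic.columns}
    none_mask = reference["outc_cod"] == ""
    outc_rows["unknown"] = {
        col: int(indic.loc[none_mask, col].sum()) for col in indic.columns
    }
    outcome = pd.DataFrame.from_dict(outc_rows, orient="index", columns=indic.columns)

    country = reference["country"].replace("", "unknown")
    recs = []
    for d in list(drugs) + ["all"]:
        counts = country[indic[d]].value_counts()
        top = counts.head(top_k_countries)
        for rank, (name, n) in enumerate(top.items(), start=1):
            recs.append({
                "drug": d, "rank": rank, "country": name, "count": int(n),
                "pct": 100.0 * n / totals[d] if totals[d] else float("nan"),
            })
    countries = pd.DataFrame(
        recs, columns=["drug", "rank", "country", "count", "pct"]
    )

    return DescriptiveSummary(
        age=_crosstab(age_band, indic, AGE_BIN_LABELS),
        weight=_crosstab(weight_band, indic, WEIGHT_BIN_LABELS),
        reporter=_crosstab(reporter, indic, reporter_order),
        outcome=outcome,
        countries=countries,
        totals=totals,
    )


def annual_trend(
    reference: pd.DataFrame,
    drugs: Sequence[str] | None = None,
    date_window: tuple[datetime.date, datetime.date] | None = None,
) -> pd.DataFrame:
    """Per-drug report counts by calendar year of FDA_DT.

    Years with no reports appear with count 0 across the window (taken from
    the data extent when not given).  Columns are drugs plus ``all``.
    """
    if drugs is None:
        drugs = sorted({d for t in reference["asms"] for d in t})
    if date_window is not None:
        y0, y1 = date_window[0].year, date_window[1].year
    elif len(reference):
        y0 = int(reference["fda_dt"].dt.year.min())
        y1 = int(reference["fda_dt"].dt.year.max())
    else:
        raise ValueError("empty reference and no date_window to span")
    years = list(range(y0, y1 + 1))

    indic = _drug_indicator(reference, drugs)
    year = reference["fda_dt"].dt.year
    out = pd.DataFrame(0, index=pd.Index(years, name="year"), columns=indic.columns)
    for col in indic.columns:
        counts = year[indic[col]].value_counts()
        for y, n in counts.items():
            if y0 <= int(y) <= y1:
                out.loc[int(y), col] = int(n)
    return out
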