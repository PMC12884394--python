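"""Reading, writing and deduplicating FAERS-style quarterly ASCII tables.

FAERS quarterly extracts ship as "$"-delimited text files with a header row.
Three tables matter here: DEMO (one row per report version: PRIMARYID, CASEID,
FDA_DT and demographics), DRUG (drug mentions with a role code: PS primary
suspect, SS secondary suspect, C concomitant, I interacting) and REAC (MedDRA
Preferred-Term event mentions).  Parsing follows a quarantine-not-crash policy:
every data line becomes either a typed row or a quarantine entry with a reason,
and the two counts always add up to the number of data lines.  Hard errors are
reserved for structural problems such as a missing mandatory column.

A FAERS case (CASEID) may appear several times as amended report versions with
different PRIMARYID/FDA_DT.  ``deduplicate`` keeps, per CASEID, the row with the
most recent FDA_DT, breaking date ties by the higher PRIMARYID.  Rows with a
missing FDA_DT are treated as older than any dated row for the same case.

Only the modern PRIMARYID/CASEID schema (2012Q4 onward) is supported; legacy
ISR-keyed files are out of scope.
"""

from __future__ import annotations

import csv
import io as _io
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np
import pandas as pd

__all__ = [
    "ParseResult",
    "JoinedReports",
    "parse_table",
    "deduplicate",
    "join_reports",
    "write_table",
]

#: per-table column layout: (required header names, optional header names)
TABLE_SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "DEMO": (
        ("PRIMARYID", "CASEID", "FDA_DT"),
        ("AGE", "AGE_COD", "SEX", "WT", "WT_COD", "OCCP_COD",
         "REPORTER_COUNTRY", "OUTC_COD"),
    ),
    "DRUG": (("PRIMARYID", "DRUGNAME", "ROLE_COD"), ("PROD_AI",)),
    "REAC": (("PRIMARYID", "PT"), ()),
}

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"CA", "DE", "DS", "LT", "HO", "OT", "RI"})

#: values treated as missing after whitespace stripping
_MISSING = frozenset({"", "NA"})

_DATE_MIN = datetime.date(1900, 1, 1)


@dataclass
class ParseResult:
    """Typed rows plus the quarantine log for one parsed table."""

    table: str
    frame: pd.DataFrame
    quarantine: pd.DataFrame

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def n_quarantined(self) -> int:
        return len(self.quarantine)


@dataclass
class JoinedReports:
    """Deduplicated DEMO rows with their attached drug and event mentions."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    orphans: dict = field(default_factory=dict)


def _clean(value: str) -> str:
    value = value.strip()
    return "" if value in _MISSING else value


def _parse_date(token: str) -> datetime.date | None:
    """Parse an 8-digit YYYYMMDD token; None when malformed or out of range."""
    if len(token) != 8 or not token.isdigit():
        return None
    try:
        d = datetime.date(int(token[:4]), int(token[4:6]), int(token[6:8]))
    except ValueError:
        return None
    if d < _DATE_MIN or d > datetime.date.today():
        return None
    return d


def _parse_positive_int(token: str) -> int | None:
    if not token.isdigit():
        return None
    value = int(token)
    return value if value > 0 else None


def _parse_nonneg_float(token: str) -> float | None:
    try:
        value = float(token)
    except ValueError:
        return None
    return value if value >= 0 and np.isfinite(value) else None


def parse_table(
    source: Union[str, Path, IO[str]],
    table: str,
    delimiter: str = "$",
) -> ParseResult:
    """Parse one FAERS-style ASCII table into a typed DataFrame.

    Parameters
    ----------
    source
        Path to a text file, or an open text stream.  The first line must be a
        header naming the columns (case-insensitive).
    table
        One of ``"DEMO"``, ``"DRUG"``, ``"REAC"``.
    delimiter
        Field separator; FAERS convention is ``"$"``.

    Returns
    -------
    ParseResult
        ``frame`` holds the typed rows; ``quarantine`` holds one entry per
        rejected line with columns ``line``, ``reason``, ``raw``.  Their row
        counts sum to the number of data lines read.

    Raises
    ------
    ValueError
        If ``table`` is unknown or a mandatory column is absent from the
        header (structural error — the file cannot be interpreted).
    """
    table = table.upper()
    if table not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {table!r}; expected DEMO/DRUG/REAC")
    required, optional = TABLE_SCHEMAS[table]

    if isinstance(source, (str, Path)):
        handle: IO[str] = open(source, "r", newline="")
        close = True
    else:
        handle, close = source, False
    try:
        reader = csv.reader(handle, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{table}: empty input, no header line")
        colidx = {name.strip().upper(): i for i, name in enumerate(header)}
        for col in required:
            if col not in colidx:
                raise ValueError(f"{table}: mandatory column {col} missing from header")
        present = [c for c in required + optional if c in colidx]

        rows: list[dict] = []
        bad: list[dict] = []
        for lineno, record in enumerate(reader, start=2):
            if not record or (len(record) == 1 and not record[0].strip()):
                continue  # blank trailing line
            raw = delimiter.join(record)
            if len(record) < max(colidx[c] for c in present) + 1:
                bad.append({"line": lineno, "reason": "wrong field count", "raw": raw})
                continue
            values = {c: _clean(record[colidx[c]]) for c in present}
            parsed, reason = _parse_row(table, values)
            if reason is not None:
                bad.append({"line": lineno, "reason": reason, "raw": raw})
            else:
                rows.append(parsed)
    finally:
        if close:
            handle.close()

    frame = _typed_frame(table, rows)
    quarantine = pd.DataFrame(bad, columns=["line", "reason", "raw"])
    return ParseResult(table=table, frame=frame, quarantine=quarantine)


def _parse_row(table: str, v: dict[str, str]) -> tuple[dict | None, str | None]:
    """Validate one cleaned row; returns (typed dict, None) or (None, reason)."""
    pid = _parse_positive_int(v["PRIMARYID"])
    if pid is None:
        return None, "bad primaryid"

    if table == "DEMO":
        caseid = _parse_positive_int(v["CASEID"])
        if caseid is None:
            return None, "bad caseid"
        fda_dt = None
        if v["FDA_DT"]:
            fda_dt = _parse_date(v["FDA_DT"])
            if fda_dt is None:
                return None, "bad date"
        age = wt = None
        if v.get("AGE", ""):
            age = _parse_nonneg_float(v["AGE"])
            if age is None:
                return None, "bad age"
        if v.get("WT", ""):
            wt = _parse_nonneg_float(v["WT"])
            if wt is None:
                return None, "bad weight"
        outc = v.get("OUTC_COD", "")
        codes = sorted({c.strip().upper() for c in outc.split(",") if c.strip()})
        if any(c not in OUTCOME_CODES for c in codes):
            return None, "bad outcome code"
        return {
            "primaryid": pid,
            "caseid": caseid,
            "fda_dt": fda_dt,
            "age": age,
            "age_cod": v.get("AGE_COD", "").upper(),
            "sex": v.get("SEX", "").upper(),
            "wt": wt,
            "wt_cod": v.get("WT_COD", "").upper(),
            "occp_cod": v.get("OCCP_COD", "").upper(),
            "country": v.get("REPORTER_COUNTRY", ""),
            "outc_cod": ",".join(codes),
        }, None

    if table == "DRUG":
        role = v["ROLE_COD"].upper()
        if role not in ROLE_CODES:
            return None, "bad role code"
        if not v["DRUGNAME"]:
            return None, "empty drugname"
        return {
            "primaryid": pid,
            "drugname": v["DRUGNAME"],
            "prod_ai": v.get("PROD_AI", ""),
            "role_cod": role,
        }, None

    # REAC
    pt = " ".join(v["PT"].split())
    if not pt:
        return None, "empty pt"
    return {"primaryid": pid, "pt": pt}, None


def _typed_frame(table: str, rows: list[dict]) -> pd.DataFrame:
    if table == "DEMO":
        cols = ["primaryid", "caseid", "fda_dt", "age", "age_cod", "sex",
                "wt", "wt_cod", "occp_cod", "country", "outc_cod"]
        frame = pd.DataFrame(rows, columns=cols)
        frame["primaryid"] = frame["primaryid"].astype("int64")
        frame["caseid"] = frame["caseid"].astype("int64")
        frame["fda_dt"] = pd.to_datetime(frame["fda_dt"])
        frame["age"] = frame["age"].astype("float64")
        frame["wt"] = frame["wt"].astype("float64")
        for c in ("age_cod", "sex", "wt_cod", "occp_cod", "country", "outc_cod"):
            frame[c] = frame[c].fillna("").astype("str")
        return frame
    if table == "DRUG":
        frame = pd.DataFrame(rows, columns=["primaryid", "drugname", "prod_ai", "role_cod"])
        frame["primaryid"] = frame["primaryid"].astype("int64")
        for c in ("drugname", "prod_ai", "role_cod"):
            frame[c] = frame[c].fillna("").astype("str")
        return frame
    frame = pd.DataFrame(rows, columns=["primaryid", "pt"])
    frame["primaryid"] = frame["primaryid"].astype("int64")
    frame["pt"] = frame["pt"].fillna("").astype("str")
    return frame


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Collapse report versions to one row per CASEID.

    The retained row maximizes ``(fda_dt, primaryid)`` lexicographically:
    the most recent FDA receipt date wins, and on a date tie the higher
    PRIMARYID (later report version) wins.  Missing dates sort before any
    real date, so an undated version loses to any dated one.  The result is
    sorted by CASEID, making the operation order-invariant and idempotent.
    """
    if demo.empty:
        return demo.copy()
    ordered = demo.sort_values(
        ["caseid", "fda_dt", "primaryid"], na_position="first", kind="mergesort"
    )
    kept = ordered.groupby("caseid", sort=True).tail(1)
    return kept.sort_values("caseid", kind="mergesort").reset_index(drop=True)


def join_reports(
    demo: pd.DataFrame, drug: pd.DataFrame, reac: pd.DataFrame
) -> JoinedReports:
    """Attach drug and event mentions to (already deduplicated) DEMO rows.

    Mentions whose PRIMARYID does not appear in ``demo`` — either removed by
    deduplication or never present — are dropped and counted in ``orphans``.
    """
    pids = pd.Index(demo["primaryid"])
    drug_kept = drug[drug["primaryid"].isin(pids)].reset_index(drop=True)
    reac_kept = reac[reac["primaryid"].isin(pids)].reset_index(drop=True)
    orphans = {
        "drug": int(len(drug) - len(drug_kept)),
        "reac": int(len(reac) - len(reac_kept)),
    }
    return JoinedReports(demo=demo.reset_index(drop=True),
                         drug=drug_kept, reac=reac_kept, orphans=orphans)


def _format_number(x) -> str:
    if pd.isna(x):
        return ""
    x = float(x)
    if x.is_integer():
        return str(int(x))
    return repr(x)


def write_table(
    frame: pd.DataFrame,
    table: str,
    dest: Union[str, Path, IO[str]],
    delimiter: str = "$",
) -> None:
    """Write a typed DataFrame back out in the FAERS ASCII dialect.

    Round-trips with :func:`parse_table`: re-parsing the written file yields
    an identical typed frame.
    """
    table = table.upper()
    required, optional = TABLE_SCHEMAS[table]
    header = [c for c in required + optional]

    out = frame.copy()
    if table == "DEMO":
        out["FDA_DT"] = out["fda_dt"].dt.strftime("%Y%m%d").fillna("")
        out["AGE"] = out["age"].map(_format_number)
        out["WT"] = out["wt"].map(_format_number)
        rename = {"primaryid": "PRIMARYID", "caseid": "CASEID",
                  "age_cod": "AGE_COD", "sex": "SEX", "wt_cod": "WT_COD",
                  "occp_cod": "OCCP_COD", "country": "REPORTER_COUNTRY",
                  "outc_cod": "OUTC_COD"}
    elif table == "DRUG":
        rename = {"primaryid": "PRIMARYID", "drugname": "DRUGNAME",
                  "prod_ai": "PROD_AI", "role_cod": "ROLE_COD"}
    else:
        rename = {"primaryid": "PRIMARYID", "pt": "PT"}
    out = out.rename(columns=rename)

    if isinstance(dest, (str, Path)):
        handle: IO[str] = open(dest, "w", newline="")
        close = True
    else:
        handle, close = dest, False
    try:
        writer = csv.writer(handle, delimiter=delimiter, lineterminator="\n")
        writer.writerow(header)
        cols = [out[c].astype("str").to_numpy() for c in header]
        for row in zip(*cols):
            writer.writerow(row)
    finally:
        if close:
            handle.close()
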