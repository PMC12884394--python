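"""Shared fixtures: tiny hand-built FAERS-style frames."""

import datetime

import pandas as pd
import pytest

from faersig.cohort import CohortSpec, DrugLexicon


DEMO_DEFAULTS = dict(age=None, age_cod="", sex="M", wt=None, wt_cod="",
                     occp_cod="MD", country="US", outc_cod="")


def demo_frame(rows):
    """Build a typed DEMO frame from dicts with sensible defaults.

    Each dict needs at least primaryid/caseid/fda_dt (date or None).
    """
    full = []
    for row in rows:
        r = {**DEMO_DEFAULTS, **row}
        full.append(r)
    frame = pd.DataFrame(full)
    frame["primaryid"] = frame["primaryid"].astype("int64")
    frame["caseid"] = frame["caseid"].astype("int64")
    frame["fda_dt"] = pd.to_datetime(frame["fda_dt"])
    frame["age"] = frame["age"].astype("float64")
    frame["wt"] = frame["wt"].astype("float64")
    for c in ("age_cod", "sex", "wt_cod", "occp_cod", "country", "outc_cod"):
        frame[c] = frame[c].fillna("").astype("str")
    return frame[["primaryid", "caseid", "fda_dt", "age", "age_cod", "sex",
                  "wt", "wt_cod", "occp_cod", "country", "outc_cod"]]


def drug_frame(rows):
    """(primaryid, drugname, prod_ai, role_cod) tuples → typed DRUG frame."""
    frame = pd.DataFrame(rows, columns=["primaryid", "drugname", "prod_ai",
                                        "role_cod"])
    frame["primaryid"] = frame["primaryid"].astype("int64")
    return frame


def reac_frame(rows):
    """(primaryid, pt) tuples → typed REAC frame."""
    frame = pd.DataFrame(rows, columns=["primaryid", "pt"])
    frame["primaryid"] = frame["primaryid"].astype("int64")
    return frame


@pytest.fixture(scope="session")
def lexicon():
    return DrugLexicon.default()


@pytest.fixture(scope="session")
def wide_window_spec():
    return CohortSpec(
        target_pt="Male infertility",
        date_window=(datetime.date(2000, 1, 1), datetime.date(2024, 12, 31)),
    )
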