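"""Reference numbers from a published ten-drug antiseizure screen.

These are the headline summary figures of the published FAERS
disproportionality screen of antiseizure medications against the MedDRA
Preferred Term "Male infertility" (2004 Q1 – 2024 Q3) that this package
re-implements.  They are used as worked-example inputs: the per-drug case
counts and printed interval bounds let the criteria logic and presentation
formatters be exercised on real published values without any FAERS download.

The full-scale drug-level estimates themselves are not reproducible at test
scale (they require the complete 20-year extract), so nothing here is an
expected output of the statistical pipeline — only input data for the
criteria and formatting layers.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "REFERENCE_TOTAL",
    "CASE_COUNTS",
    "DRUG_REPORT_TOTALS",
    "PUBLISHED_SIGNALS",
    "PublishedSignal",
]

#: deduplicated reports with a study ASM as primary suspect
REFERENCE_TOTAL = 81618

#: reported "Male infertility" cases per drug (drugs with none → 0)
CASE_COUNTS: dict[str, int] = {
    "valproic acid": 20,
    "carbamazepine": 19,
    "lamotrigine": 8,
    "levetiracetam": 7,
    "oxcarbazepine": 3,
    "phenytoin": 1,
    "clonazepam": 1,
    "topiramate": 1,
    "phenobarbital": 0,
    "diazepam": 0,
}

#: per-drug report totals of the reference dataset (all events)
DRUG_REPORT_TOTALS: dict[str, int] = {
    "levetiracetam": 19388,
    "valproic acid": 14284,
    "lamotrigine": 13817,
    "carbamazepine": 11178,
    "clonazepam": 7063,
    "phenytoin": 7047,
    "topiramate": 5193,
    "oxcarbazepine": 3648,
    "phenobarbital": 0,
    "diazepam": 0,
}


@dataclass(frozen=True)
class PublishedSignal:
    """Printed ROR/IC estimates for one drug flagged positive in the screen."""

    drug: str
    ror: float
    ror_lo95: float
    ror_hi95: float
    ic: float
    ic025: float


#: the five drugs reported as positive under the joint ROR/BCPNN criterion
PUBLISHED_SIGNALS: tuple[PublishedSignal, ...] = (
    PublishedSignal("carbamazepine", 8.73, 5.54, 13.76, 3.10, 2.45),
    PublishedSignal("valproic acid", 6.82, 4.38, 10.63, 2.74, 2.10),
    PublishedSignal("oxcarbazepine", 4.72, 1.52, 14.65, 2.23, 0.79),
    PublishedSignal("lamotrigine", 3.39, 1.69, 6.81, 1.75, 0.79),
    PublishedSignal("levetiracetam", 2.64, 1.25, 5.55, 1.39, 0.37),
)
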