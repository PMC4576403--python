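"""Clinical records: one row per trial subject.

The clinical table is a delimited text file with columns ``subject_id``,
``arm`` (RTX = rituximab, CYC = cyclophosphamide), ``visit`` and ``outcome``
(``remission`` = complete remission at month 6, the trial's primary
endpoint, or ``failure``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

ARMS = ("RTX", "CYC")
OUTCOMES = ("remission", "failure")

_REQUIRED_COLUMNS = ("subject_id", "arm", "outcome")


class ClinicalDataError(ValueError):
    """Invalid clinical table content."""


@dataclass
class PatientRecord:
    """One trial subject: arm, primary-endpoint outcome, and baseline GI."""

    subject_id: str
    arm: str
    outcome: str
    gi: float | None = None
    diagnosis: str | None = None
    serotype: str | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ClinicalDataError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if self.outcome not in OUTCOMES:
            raise ClinicalDataError(
                f"unknown outcome {self.outcome!r}; expected one of {OUTCOMES}"
            )

    @property
    def remitted(self) -> bool:
        return self.outcome == "remission"


def read_clinical(path: str | Path, sep: str = ",") -> list[PatientRecord]:
    """Read and validate a clinical table.

    Arm and outcome values are case-folded (``Remission`` and ``rtx`` are
    accepted); unknown vocabulary and duplicated subject ids are rejected.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ClinicalDataError(f"{path}: missing required column(s) {missing}")

    dupes = df["subject_id"][df["subject_id"].duplicated()].unique().tolist()
    if dupes:
        raise ClinicalDataError(f"{path}: duplicated subject_id(s) {dupes}")

    records = []
    for row in df.itertuples(index=False):
        records.append(
            PatientRecord(
                subject_id=str(row.subject_id),
                arm=str(row.arm).strip().upper(),
                outcome=str(row.outcome).strip().lower(),
                diagnosis=getattr(row, "diagnosis", None),
                serotype=getattr(row, "serotype", None),
            )
        )
    return records
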