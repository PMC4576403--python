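"""The Granularity Index (GI).

GI is the signed difference between the percentage of hypergranular
granulocytes (maximal side scatter, level 4) and hypogranular granulocytes
(intermediate side scatter) among all white blood cells in a sample, ranging
from −100 % to +100 %.  E.g. a sample that is 40 % hypergranular and 20 %
hypogranular has GI = 20 %.  A positive GI means granulocytes skew toward
high internal granularity; a negative GI means they skew hypogranular.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .autogate import SampleGating
from .clinical import PatientRecord
from .popquery import BUILTIN_QUERY_TEXT, apply_query, parse_query

__all__ = ["GIRecord", "granularity_index", "gi_for_sample", "baseline_gi"]

log = logging.getLogger(__name__)

_HYPER = parse_query(
    BUILTIN_QUERY_TEXT["Hypergranular granulocytes"], name="Hypergranular granulocytes"
)
_HYPO = parse_query(
    BUILTIN_QUERY_TEXT["Hypogranular granulocytes"], name="Hypogranular granulocytes"
)

#: Visit labels accepted as baseline, in priority order (screening wins).
BASELINE_VISITS = ("screening", "day0")


@dataclass(frozen=True)
class GIRecord:
    """Per-sample granulocyte percentages and their Granularity Index."""

    subject_id: str | None
    visit: str | None
    pct_hyper: float
    pct_hypo: float
    gi: float


def granularity_index(pct_hyper: float, pct_hypo: float) -> float:
    """Signed GI = hypergranular % − hypogranular %.

    Both inputs are percentages of total white blood cells in [0, 100]; the
    result lies in [−100, 100].
    """
    for name, v in (("pct_hyper", pct_hyper), ("pct_hypo", pct_hypo)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name}={v} outside [0, 100]")
    return float(pct_hyper) - float(pct_hypo)


def gi_for_sample(gating: SampleGating) -> GIRecord:
    """Compute the GI of one auto-gated sample.

    The hypergranular and hypogranular percentages come from the built-in
    population queries (SSC level 4 vs. intermediate-SSC patterns) applied
    to the sample's cluster profiles.
    """
    pct_hyper = apply_query(gating, _HYPER)
    pct_hypo = apply_query(gating, _HYPO)
    return GIRecord(
        subject_id=gating.subject_id,
        visit=gating.visit,
        pct_hyper=pct_hyper,
        pct_hypo=pct_hypo,
        gi=granularity_index(pct_hyper, pct_hypo),
    )


def baseline_gi(
    gi_records: list[GIRecord],
    clinical: list[PatientRecord],
) -> list[PatientRecord]:
    """Attach each subject's baseline GI to their clinical record.

    Keeps only baseline-visit GI records (screening; day 0 if no screening
    sample exists).  Subjects without a baseline measurement are excluded
    with a logged count; a subject with duplicate baseline gatings for the
    same visit is an error.
    """
    by_subject: dict[str, dict[str, GIRecord]] = {}
    for rec in gi_records:
        if rec.visit not in BASELINE_VISITS:
            continue
        visits = by_subject.setdefault(rec.subject_id, {})
        if rec.visit in visits:
            raise ValueError(
                f"duplicate baseline gating for subject {rec.subject_id!r} "
                f"visit {rec.visit!r}"
            )
        visits[rec.visit] = rec

    out: list[PatientRecord] = []
    excluded = 0
    for patient in clinical:
        visits = by_subject.get(patient.subject_id)
        if not visits:
            excluded += 1
            continue
        for visit in BASELINE_VISITS:  # screening takes priority over day0
            if visit in visits:
                out.append(replace(patient, gi=visits[visit].gi))
                break
    if excluded:
        log.info(
            "%d of %d subjects had no baseline flow cytometry and were excluded",
            excluded,
            len(clinical),
        )
    if not out:
        log.warning("no subjects with baseline gating")
    return out
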