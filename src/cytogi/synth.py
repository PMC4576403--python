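"""Synthetic flow-cytometry samples and clinical cohorts.

The generator emulates the structure the downstream analysis assumes: each
whole-blood sample is a mixture of leukocyte populations (lymphocytes,
monocytes, hypergranular and hypogranular granulocytes, plus low-scatter
debris), each modelled as a diagonal-covariance Gaussian on the raw
instrument scale.  At the cohort level, every patient carries a latent
Granularity Index (GI = hypergranular% − hypogranular% of all events) that
(i) sets the granulocyte split of their event cloud and (ii) drives their
probability of complete remission through an arm-specific logistic link:
remission probability rises with GI under rituximab (RTX) and falls with GI
under cyclophosphamide (CYC).

Populations are deliberately compact (channel sd ~10–35 units on a 0–1023
scale) and well separated, so that the fixed-grid density gating stage can
resolve them; real cytometry data is messier in ways documented in the
methods note.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.special import expit, logit

from .clinical import PatientRecord
from .events import CHANNELS, DEFAULT_RANGE, EventTable
from .fcs import write_fcs as _write_fcs

__all__ = [
    "PopulationSpec",
    "CohortConfig",
    "default_template",
    "template_for_gi",
    "simulate_events",
    "simulate_cohort",
    "write_fcs",
    "write_cohort",
]

_POPULATIONS = (
    "lymphocyte",
    "monocyte",
    "hypergranular_granulocyte",
    "hypogranular_granulocyte",
    "debris",
)

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class PopulationSpec:
    """One Gaussian component of a sample's event mixture.

    ``channel_means``/``channel_sds`` are on the raw instrument scale and map
    positionally onto :data:`cytogi.events.CHANNELS`.
    """

    name: str
    fraction: float
    channel_means: tuple[float, ...]
    channel_sds: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.name not in _POPULATIONS:
            raise ValueError(
                f"unknown population {self.name!r}; expected one of {_POPULATIONS}"
            )
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction {self.fraction} outside [0, 1]")
        if len(self.channel_means) != len(self.channel_sds):
            raise ValueError("channel_means and channel_sds must have equal length")
        if any(s <= 0 for s in self.channel_sds):
            raise ValueError("all channel sds must be strictly positive")


#                       FSC   SSC  CD19  CD21  CD23   CD5  CD1c
_MEANS = {
    "debris":                    (40,   30,   40,   40,   40,   40,   40),
    "lymphocyte":                (200,  80,  420,  300,  260,  500,  120),
    "monocyte":                  (620, 150,   90,  120,  200,  160,  350),
    "hypogranular_granulocyte":  (450, 490,   70,   80,   90,   80,   70),
    "hypergranular_granulocyte": (520, 840,   70,   80,   90,   80,   70),
}
_SDS = {
    "debris":                    (10,  8, 10, 10, 10, 10, 10),
    "lymphocyte":                (22, 16, 30, 26, 24, 30, 18),
    "monocyte":                  (26, 20, 13, 13, 14, 14, 16),
    "hypogranular_granulocyte":  (26, 26, 12, 12, 12, 12, 12),
    "hypergranular_granulocyte": (26, 28, 12, 12, 12, 12, 12),
}

# Default non-granulocyte composition of a sample.
_LYMPH_FRAC = 0.22
_MONO_FRAC = 0.07
_DEBRIS_FRAC = 0.05


def _spec(name: str, fraction: float) -> PopulationSpec:
    return PopulationSpec(name, fraction, _MEANS[name], _SDS[name])


def template_for_gi(
    gi: float,
    lymph_frac: float = _LYMPH_FRAC,
    mono_frac: float = _MONO_FRAC,
    debris_frac: float = _DEBRIS_FRAC,
) -> list[PopulationSpec]:
    """Population mixture realizing a given Granularity Index.

    The granulocyte total ``G = 1 − lymph − mono − debris`` is split so that
    (hyper − hypo) fraction equals ``gi``/100 exactly, which makes the
    measured GI an unbiased estimator of the latent value.
    """
    gran = 1.0 - lymph_frac - mono_frac - debris_frac
    if gran <= 0:
        raise ValueError("non-granulocyte fractions leave no granulocytes")
    bound = 100.0 * gran
    if abs(gi) > bound:
        raise ValueError(f"gi {gi} exceeds attainable bound ±{bound:.1f}")
    hyper = (gran + gi / 100.0) / 2.0
    hypo = (gran - gi / 100.0) / 2.0
    return [
        _spec("lymphocyte", lymph_frac),
        _spec("monocyte", mono_frac),
        _spec("hypergranular_granulocyte", hyper),
        _spec("hypogranular_granulocyte", hypo),
        _spec("debris", debris_frac),
    ]


def default_template() -> list[PopulationSpec]:
    """The default 4-population + debris mixture (latent GI = +20)."""
    return template_for_gi(20.0)


def _validate_specs(specs: list[PopulationSpec]) -> np.ndarray:
    if not specs:
        raise ValueError("at least one PopulationSpec required")
    fractions = np.array([s.fraction for s in specs], dtype=float)
    if abs(fractions.sum() - 1.0) > _FRACTION_TOL:
        raise ValueError(f"population fractions sum to {fractions.sum()}, not 1")
    return fractions


def simulate_events(
    specs: list[PopulationSpec],
    n_events: int,
    seed: int | np.random.Generator,
) -> EventTable:
    """Draw one sample's event cloud from a Gaussian-mixture template.

    Component counts are multinomial in the template fractions; values are
    clipped to the declared instrument range ``[0, 1023]``.  Ground-truth
    population labels are kept on the returned table (hidden from the gating,
    used only for validation).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    fractions = _validate_specs(specs)
    rng = np.random.default_rng(seed)

    counts = rng.multinomial(n_events, fractions)
    blocks, labels = [], []
    for spec_i, count in zip(specs, counts):
        if count == 0:
            continue
        means = np.asarray(spec_i.channel_means, dtype=float)
        sds = np.asarray(spec_i.channel_sds, dtype=float)
        blocks.append(rng.normal(means, sds, size=(count, means.size)))
        labels.extend([spec_i.name] * count)
    values = np.vstack(blocks)
    values = np.clip(values, 0.0, DEFAULT_RANGE - 1.0)
    order = rng.permutation(n_events)
    return EventTable(
        values=values[order],
        channels=CHANNELS,
        labels=np.asarray(labels, dtype=object)[order],
    )


def _slope_for_gap(effect: float, sd: float, baseline: float) -> float:
    """Logistic slope whose remitter/non-remitter mean gap equals ``effect``.

    For latent GI ~ Normal(mu, sd) and P(remission | g) =
    expit(logit(baseline) + b (g − mu)), the realized gap
    E[g | remission] − E[g | failure] = cov(g, Y) / (p̄ (1 − p̄)) is a
    monotone, saturating function of b; solve for b by bisection on a
    Gauss-Hermite quadrature of the gap.
    """
    if effect == 0.0:
        return 0.0
    alpha = logit(np.clip(baseline, 1e-12, 1 - 1e-12))
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)

    def gap(b: float) -> float:
        p = expit(alpha + b * sd * nodes)
        pbar = float(weights @ p) / weights.sum()
        cov = float(weights @ (sd * nodes * p)) / weights.sum()
        return cov / (pbar * (1.0 - pbar))

    from scipy.optimize import brentq

    target = abs(effect)
    b_hi = 20.0 / sd
    if gap(b_hi) <= target:
        raise ValueError(
            f"gi effect {effect} not attainable with gi_sd={sd} "
            f"(saturates near {gap(b_hi):.1f})"
        )
    b = brentq(lambda b: gap(b) - target, 0.0, b_hi, xtol=1e-10)
    return math.copysign(b, effect)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated two-arm treatment cohort.

    ``gi_effect_rtx``/``gi_effect_cyc`` are the mean-GI gaps (percent units)
    between remitters and non-remitters in each arm; the generator realizes
    them through a logistic outcome model whose arm-specific slope is solved
    numerically so the realized gap matches the parameter.  Defaults mirror
    the reversed-direction pattern the analysis is designed to detect:
    higher GI favors remission on RTX, lower GI favors remission on CYC.
    """

    n_patients: int = 187
    p_rtx: float = 0.5
    gi_effect_rtx: float = 30.0
    gi_effect_cyc: float = -30.0
    gi_mean: float = 20.0
    gi_sd: float = 35.0
    baseline_remission: float = 0.58
    n_events: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name in ("p_rtx", "baseline_remission"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.gi_sd <= 0:
            raise ValueError("gi_sd must be positive")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[PatientRecord], list[EventTable]]:
    """Simulate a cohort of patients with events, arms and outcomes.

    Per patient: arm ~ Bernoulli(``p_rtx``); lymphocyte and monocyte
    fractions jittered around their template values (inter-patient leukocyte
    composition varies); latent GI ~ Normal(``gi_mean``, ``gi_sd``), clipped
    so each granulocyte subset keeps at least 1 % of events; outcome ~
    Bernoulli(expit(logit(``baseline_remission``) + slope_arm · (GI −
    ``gi_mean``))); and an event cloud whose granulocyte split realizes the
    latent GI.  All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    slope = {
        "RTX": _slope_for_gap(config.gi_effect_rtx, config.gi_sd, config.baseline_remission),
        "CYC": _slope_for_gap(config.gi_effect_cyc, config.gi_sd, config.baseline_remission),
    }
    alpha = logit(np.clip(config.baseline_remission, 1e-12, 1 - 1e-12))

    width = len(str(config.n_patients))
    records: list[PatientRecord] = []
    tables: list[EventTable] = []
    for i in range(config.n_patients):
        subject = f"S{i + 1:0{width}d}"
        arm = "RTX" if rng.random() < config.p_rtx else "CYC"
        lymph = float(np.clip(rng.normal(_LYMPH_FRAC, 0.04), 0.12, 0.32))
        mono = float(np.clip(rng.normal(_MONO_FRAC, 0.015), 0.035, 0.11))
        gran_total = 1.0 - lymph - mono - _DEBRIS_FRAC
        gi_bound = 100.0 * gran_total - 2.0  # keep hyper and hypo each >= 1 %
        gi = float(np.clip(rng.normal(config.gi_mean, config.gi_sd), -gi_bound, gi_bound))
        p_rem = float(expit(alpha + slope[arm] * (gi - config.gi_mean)))
        outcome = "remission" if rng.random() < p_rem else "failure"

        table = simulate_events(
            template_for_gi(gi, lymph_frac=lymph, mono_frac=mono),
            config.n_events,
            rng,
        )
        table = replace(table, subject_id=subject, visit="screening", latent_gi=gi)
        records.append(PatientRecord(subject_id=subject, arm=arm, outcome=outcome))
        tables.append(table)
    return records, tables


def write_fcs(events: EventTable, path: str | Path) -> None:
    """Write one simulated sample as a standard FCS 3.1 file."""
    _write_fcs(events, path)


def write_cohort(
    records: list[PatientRecord],
    tables: list[EventTable],
    outdir: str | Path,
    ground_truth: bool = True,
) -> Path:
    """Write a simulated cohort to disk in standard formats.

    Produces ``clinical.csv`` (subject_id, arm, visit, outcome), one FCS file
    per sample under ``fcs/``, and — for test use only — a ground-truth
    sidecar ``ground_truth.csv`` (subject_id, latent_gi, labels_path) with
    per-event labels under ``labels/``.
    """
    outdir = Path(outdir)
    fcs_dir = outdir / "fcs"
    fcs_dir.mkdir(parents=True, exist_ok=True)

    with open(outdir / "clinical.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "arm", "visit", "outcome"])
        for rec in records:
            writer.writerow([rec.subject_id, rec.arm, "screening", rec.outcome])

    truth_rows = []
    for table in tables:
        _write_fcs(table, fcs_dir / f"{table.subject_id}_{table.visit}.fcs")
        if ground_truth and table.labels is not None:
            labels_dir = outdir / "labels"
            labels_dir.mkdir(exist_ok=True)
            labels_path = labels_dir / f"{table.subject_id}_{table.visit}.csv"
            with open(labels_path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["event_index", "label"])
                for j, lab in enumerate(table.labels):
                    writer.writerow([j, lab])
            truth_rows.append(
                [table.subject_id, f"{table.latent_gi:.6g}", str(labels_path.relative_to(outdir))]
            )
    if ground_truth and truth_rows:
        with open(outdir / "ground_truth.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["subject_id", "latent_gi", "labels_path"])
            writer.writerows(truth_rows)
    return outdir
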