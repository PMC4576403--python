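"""Cutoff, likelihood-ratio and stratification statistics.

Implements the inferential machinery for a continuous baseline biomarker
(here the Granularity Index) and a binary treatment outcome:

* exact two-tailed Fisher test (probability-mass convention, computed in
  exact integer arithmetic over the hypergeometric support);
* positive likelihood ratios with 95 % log-method confidence intervals;
* two-sample Kruskal-Wallis rank test (tie-corrected, chi-square 1 df);
* Pearson r-squared;
* Youden-index optimal cutpoints (J = sensitivity + specificity − 1,
  maximized over candidate thresholds);
* three-band biomarker stratification with per-band between-arm comparisons;
* a profiled-design projection: the overall remission count expected if each
  outer band received its favored arm while the middle band kept its
  observed outcomes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .clinical import PatientRecord

__all__ = [
    "ContingencyTable2x2",
    "CutoffResult",
    "LikelihoodRatioResult",
    "StratumSummary",
    "ProjectionResult",
    "fisher_exact_two_tailed",
    "likelihood_ratio",
    "kruskal_wallis_two_sample",
    "pearson_r2",
    "youden_cutoff",
    "derive_gi_cutoffs",
    "derive_band_cutoffs",
    "stratify",
    "crossover_detected",
    "profiled_projection",
]

log = logging.getLogger(__name__)

BELOW_FLAGS_POSITIVE = "below_flags_positive"
ABOVE_FLAGS_POSITIVE = "above_flags_positive"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = classification/arm, cols = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name}={v} must be a nonnegative integer")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table total must be >= 1")


def fisher_exact_two_tailed(
    table: ContingencyTable2x2 | list[list[int]] | tuple,
) -> float:
    """Two-tailed Fisher's exact p-value.

    Sums, over the hypergeometric support with the observed margins, the
    probability of every table at most as probable as the observed one (the
    probability-mass two-sided convention).  The comparison is done on exact
    integer numerators (``math.comb`` products over a common denominator), so
    probability ties resolve exactly and no floating-point slack is needed.

    A table with an all-zero margin carries no information; p = 1 with a
    warning.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or b + d == 0:
        log.warning("degenerate 2x2 table with an empty margin; p = 1")
        return 1.0

    observed = math.comb(r1, a) * math.comb(r2, c)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    numerator = 0
    for k in range(lo, hi + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w <= observed:
            numerator += w
    return numerator / math.comb(n, c1)


@dataclass(frozen=True)
class LikelihoodRatioResult:
    """A positive likelihood ratio with 95 % confidence bounds.

    ``lr`` is P(flagged | positive) / P(flagged | negative).  Bounds are NaN
    for boundary inputs (no flagged positives or no flagged negatives) where
    the log-method interval is undefined.
    """

    lr: float
    ci_low: float
    ci_high: float


def likelihood_ratio(a: int, m: int, b: int, n: int) -> LikelihoodRatioResult:
    """Positive likelihood ratio (a/m)/(b/n) with a 95 % log-method CI.

    ``a`` of ``m`` positives and ``b`` of ``n`` negatives are flagged by the
    marker.  CI: exp(ln LR ± 1.96·sqrt((1 − a/m)/a + (1 − b/n)/b)).  With
    ``a = 0`` or ``b = 0`` the ratio degenerates (0 or infinity); an explicit
    boundary result with NaN bounds is returned, with a warning.
    """
    if not (0 <= a <= m and 0 <= b <= n) or m == 0 or n == 0:
        raise ValueError(f"invalid counts a={a}, m={m}, b={b}, n={n}")
    if a == 0 or b == 0:
        log.warning("boundary likelihood ratio (a=%d, b=%d); CI undefined", a, b)
        lr = 0.0 if a == 0 else math.inf
        return LikelihoodRatioResult(lr=lr, ci_low=math.nan, ci_high=math.nan)
    sens, fpr = a / m, b / n
    lr = sens / fpr
    se = math.sqrt((1 - sens) / a + (1 - fpr) / b)
    return LikelihoodRatioResult(
        lr=lr,
        ci_low=math.exp(math.log(lr) - 1.96 * se),
        ci_high=math.exp(math.log(lr) + 1.96 * se),
    )


def kruskal_wallis_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kruskal-Wallis rank test (midrank ties, chi-square 1 df).

    Returns ``(H, p)``.  If every value across both groups is identical the
    statistic carries no information: ``(0.0, 1.0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.ptp(np.concatenate([x, y])) == 0.0:
        return 0.0, 1.0
    h, p = sps.kruskal(x, y)
    return float(h), float(p)


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation coefficient in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("r^2 undefined for a zero-variance input")
    r = sps.pearsonr(x, y).statistic
    return float(r * r)


@dataclass(frozen=True)
class CutoffResult:
    """An optimal biomarker threshold and its operating characteristics."""

    threshold: float
    direction: str
    youden_j: float
    sensitivity: float
    specificity: float
    n_flagged: int


def youden_cutoff(values, labels, direction: str) -> CutoffResult:
    """Optimal cutpoint by the Youden index.

    ``labels`` mark positives (the class the flag should catch).  With
    ``direction='below_flags_positive'`` a subject is flagged when their
    value is below the threshold; ``'above_flags_positive'`` flags above.
    Candidate thresholds are the midpoints between consecutive distinct
    sorted values plus ±infinity; the threshold maximizing
    J = sensitivity + specificity − 1 is returned, ties broken toward the
    threshold flagging fewer subjects.
    """
    if direction not in (BELOW_FLAGS_POSITIVE, ABOVE_FLAGS_POSITIVE):
        raise ValueError(f"unknown direction {direction!r}")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")

    distinct = np.unique(values)
    candidates = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    best: CutoffResult | None = None
    for t in candidates:
        flagged = values < t if direction == BELOW_FLAGS_POSITIVE else values > t
        sens = float(np.sum(flagged & labels)) / n_pos
        spec = float(np.sum(~flagged & ~labels)) / n_neg
        j = sens + spec - 1.0
        n_flagged = int(flagged.sum())
        if (
            best is None
            or j > best.youden_j + 1e-12
            or (abs(j - best.youden_j) <= 1e-12 and n_flagged < best.n_flagged)
        ):
            best = CutoffResult(
                threshold=float(t),
                direction=direction,
                youden_j=j,
                sensitivity=sens,
                specificity=spec,
                n_flagged=n_flagged,
            )
    assert best is not None
    return best


def derive_gi_cutoffs(
    patients: list[PatientRecord], arm: str = "RTX"
) -> tuple[CutoffResult, CutoffResult]:
    """Derive the two GI cutpoints from one arm's outcomes.

    Two separate Youden optimizations on the reference arm (rituximab by
    default): a *failure* cutoff (low GI flags failure to remit on that arm)
    and a *success* cutoff (high GI flags complete remission).  The two
    thresholds bound the low/middle/high bands used by :func:`stratify`.
    """
    members = [p for p in patients if p.arm == arm]
    if not members:
        raise ValueError(f"no patients in arm {arm!r}")
    gi = [p.gi for p in members]
    if any(v is None for v in gi):
        raise ValueError("all patients need a GI for cutoff derivation")
    failure = youden_cutoff(gi, [not p.remitted for p in members], BELOW_FLAGS_POSITIVE)
    success = youden_cutoff(gi, [p.remitted for p in members], ABOVE_FLAGS_POSITIVE)
    return failure, success


def derive_band_cutoffs(patients: list[PatientRecord]) -> tuple[float, float]:
    """Derive the low/high band boundaries, one from each arm.

    On the same arm, Youden-optimizing "low GI flags failure" and "high GI
    flags success" are mirror images of the same sweep and return the same
    threshold (an identity :func:`derive_gi_cutoffs` exposes), so a single
    arm cannot define two boundaries.  Instead each arm contributes its own
    failure-identification cutpoint — RTX failures are flagged *below* a
    threshold, CYC failures *above* one — and the sorted pair bounds the
    bands.  The zone between them, where the two arms' evidence disagrees,
    is the ambiguous middle band treated per best clinical judgment.
    """
    rtx = [p for p in patients if p.arm == "RTX"]
    cyc = [p for p in patients if p.arm == "CYC"]
    if not rtx or not cyc:
        raise ValueError("both arms required to derive band cutoffs")
    rtx_cut = youden_cutoff(
        [p.gi for p in rtx], [not p.remitted for p in rtx], BELOW_FLAGS_POSITIVE
    )
    cyc_cut = youden_cutoff(
        [p.gi for p in cyc], [not p.remitted for p in cyc], ABOVE_FLAGS_POSITIVE
    )
    lo, hi = sorted((rtx_cut.threshold, cyc_cut.threshold))
    return lo, hi


@dataclass(frozen=True)
class StratumSummary:
    """One biomarker band with per-arm outcomes and its between-arm test."""

    band: str  # 'low', 'middle' or 'high'
    gi_range: tuple[float, float]
    n_rtx: int
    remissions_rtx: int
    n_cyc: int
    remissions_cyc: int
    p_value: float | None  # None when an arm is empty in this band

    @property
    def n(self) -> int:
        return self.n_rtx + self.n_cyc

    @property
    def remissions(self) -> int:
        return self.remissions_rtx + self.remissions_cyc

    @property
    def rate_rtx(self) -> float | None:
        return self.remissions_rtx / self.n_rtx if self.n_rtx else None

    @property
    def rate_cyc(self) -> float | None:
        return self.remissions_cyc / self.n_cyc if self.n_cyc else None


def stratify(
    patients: list[PatientRecord],
    low_cut: float,
    high_cut: float,
) -> list[StratumSummary]:
    """Split patients into three biomarker bands and compare arms per band.

    Bands: low = GI at or below ``low_cut``; high = GI at or above
    ``high_cut``; middle = strictly between.  Each band gets per-arm counts,
    remission counts, and a two-tailed Fisher p for the between-arm
    comparison (None, with a warning, when a band has an empty arm).
    """
    if not low_cut < high_cut:
        raise ValueError("low_cut must be strictly below high_cut")
    missing = [p.subject_id for p in patients if p.gi is None]
    if missing:
        raise ValueError(f"patients without GI: {missing[:5]}")

    bounds = {
        "low": (-math.inf, low_cut),
        "middle": (low_cut, high_cut),
        "high": (high_cut, math.inf),
    }

    def band_of(gi: float) -> str:
        if gi <= low_cut:
            return "low"
        if gi >= high_cut:
            return "high"
        return "middle"

    summaries = []
    for band, gi_range in bounds.items():
        members = [p for p in patients if band_of(p.gi) == band]
        rtx = [p for p in members if p.arm == "RTX"]
        cyc = [p for p in members if p.arm == "CYC"]
        rem_rtx = sum(p.remitted for p in rtx)
        rem_cyc = sum(p.remitted for p in cyc)
        if rtx and cyc:
            p_value = fisher_exact_two_tailed(
                ContingencyTable2x2(
                    rem_cyc, len(cyc) - rem_cyc, rem_rtx, len(rtx) - rem_rtx
                )
            )
        else:
            log.warning("band %r has an empty arm; between-arm p undefined", band)
            p_value = None
        summaries.append(
            StratumSummary(
                band=band,
                gi_range=gi_range,
                n_rtx=len(rtx),
                remissions_rtx=rem_rtx,
                n_cyc=len(cyc),
                remissions_cyc=rem_cyc,
                p_value=p_value,
            )
        )
    return summaries


def crossover_detected(strata: list[StratumSummary], alpha: float = 0.05) -> bool:
    """True when the stratification shows a significant treatment crossover.

    Requires both outer bands to reach significance at ``alpha`` in opposite
    directions: CYC superior to RTX in the low band and RTX superior to CYC
    in the high band.
    """
    by_band = {s.band: s for s in strata}
    low, high = by_band.get("low"), by_band.get("high")
    if low is None or high is None or low.p_value is None or high.p_value is None:
        return False
    if low.rate_cyc is None or low.rate_rtx is None:
        return False
    return (
        low.p_value < alpha
        and low.rate_cyc > low.rate_rtx
        and high.p_value < alpha
        and high.rate_rtx > high.rate_cyc
    )


@dataclass(frozen=True)
class ProjectionResult:
    """Projected overall outcome under biomarker-profiled arm assignment."""

    projected_remissions: int
    projected_rate: float
    observed_remissions: int
    observed_rate: float
    n: int
    p_value: float


def profiled_projection(
    strata: list[StratumSummary],
    observed_remissions: int | None = None,
) -> ProjectionResult:
    """Project the overall remission count under a profiled design.

    Low-band patients are assumed assigned to CYC (at the band's observed
    CYC remission rate), high-band patients to RTX (observed RTX rate), and
    middle-band patients keep their observed outcomes.  The expected
    remission count is rounded to the nearest integer and compared with the
    observed total by a two-tailed Fisher test.
    """
    by_band = {s.band: s for s in strata}
    for band in ("low", "middle", "high"):
        if band not in by_band:
            raise ValueError(f"stratum {band!r} missing")
    low, middle, high = by_band["low"], by_band["middle"], by_band["high"]
    # An empty outer band contributes nothing; a populated one needs its
    # favored arm's observed rate.
    if low.n > 0 and low.rate_cyc is None:
        raise ValueError("projection undefined: CYC arm empty in populated low band")
    if high.n > 0 and high.rate_rtx is None:
        raise ValueError("projection undefined: RTX arm empty in populated high band")

    n = sum(s.n for s in strata)
    if observed_remissions is None:
        observed_remissions = sum(s.remissions for s in strata)

    expected = (
        (low.n * low.rate_cyc if low.n else 0.0)
        + (high.n * high.rate_rtx if high.n else 0.0)
        + middle.remissions
    )
    projected = int(round(expected))
    p = fisher_exact_two_tailed(
        ContingencyTable2x2(
            observed_remissions, n - observed_remissions, projected, n - projected
        )
    )
    return ProjectionResult(
        projected_remissions=projected,
        projected_rate=projected / n,
        observed_remissions=observed_remissions,
        observed_rate=observed_remissions / n,
        n=n,
        p_value=p,
    )
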