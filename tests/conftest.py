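"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive results by the most literal possible
route (exhaustive enumeration, brute-force search, hand-coded predicates) so
that they stay independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from cytogi.autogate import ClusterProfile, SampleGating
from cytogi.events import CHANNELS


def make_cluster(
    cluster_id: str, percent: float, **levels: int
) -> ClusterProfile:
    """Cluster with the given channel levels; unmentioned channels are 1."""
    full = {ch: 1 for ch in CHANNELS}
    full.update(levels)
    return ClusterProfile(
        cluster_id=cluster_id,
        levels=full,
        centroid={ch: float(lv) for ch, lv in full.items()},
        percent_of_total=percent,
    )


def make_gating(*clusters: ClusterProfile, subject="S1", visit="screening"):
    return SampleGating(
        subject_id=subject,
        visit=visit,
        clusters=list(clusters),
        n_events=1000,
    )


def random_gating(rng: np.random.Generator, n_clusters: int | None = None):
    """Random level vectors with percents summing to 100."""
    k = n_clusters or int(rng.integers(1, 9))
    raw = rng.dirichlet(np.ones(k)) * 100.0
    clusters = [
        make_cluster(
            f"C{i}",
            float(raw[i]),
            **{ch: int(rng.integers(1, 5)) for ch in CHANNELS},
        )
        for i in range(k)
    ]
    return make_gating(*clusters)


# ---------------------------------------------------------------------------
# Hand-coded population predicates (independent of the query parser).

BUILTIN_ORACLES = {
    "Total lymphocytes": lambda L: L["FSC"] <= 2 and L["SSC"] == 1,
    "CD1c+ lymphocytes": lambda L: L["FSC"] <= 2 and L["SSC"] == 1 and L["CD1c"] >= 2,
    "CD5+ lymphocytes": lambda L: L["FSC"] <= 2 and L["SSC"] == 1 and L["CD5"] >= 2,
    "CD19+ lymphocytes": lambda L: L["FSC"] <= 2 and L["SSC"] == 1 and L["CD19"] >= 2,
    "CD21+ lymphocytes": lambda L: L["FSC"] <= 2 and L["SSC"] == 1 and L["CD21"] >= 2,
    "CD23+ lymphocytes": lambda L: L["FSC"] <= 2 and L["SSC"] == 1 and L["CD23"] >= 2,
    "Total monocytes": lambda L: L["FSC"] >= 3 and L["SSC"] <= 2,
    "Total granulocytes": lambda L: (L["FSC"] >= 3 and L["SSC"] >= 3)
    or (L["FSC"] <= 2 and L["SSC"] >= 2),
    "Hypergranular granulocytes": lambda L: L["FSC"] >= 1 and L["SSC"] == 4,
    "Hypogranular granulocytes": lambda L: (L["FSC"] <= 2 and L["SSC"] == 3)
    or (L["FSC"] <= 2 and L["SSC"] == 2)
    or (L["FSC"] >= 3 and L["SSC"] == 3),
}


# ---------------------------------------------------------------------------
# Brute-force grid clustering oracle (2-channel).


def brute_force_partition(events_2d: np.ndarray, n_bins: int, min_density_fraction: float):
    """Independent re-derivation of grid-density cluster memberships.

    Dense-bin connected components via scipy.ndimage.label (8-connectivity),
    sparse events attached to the nearest dense-bin event-mean centroid on
    z-scored channels by an explicit loop.  Returns frozenset-of-frozensets
    event partition (label-invariant).
    """
    from scipy import ndimage

    x = np.asarray(events_2d, dtype=float)
    n = x.shape[0]
    lo, hi = x.min(axis=0), x.max(axis=0)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    idx = np.clip(
        np.floor((x - lo) / span * n_bins).astype(int), 0, n_bins - 1
    )
    for j in range(2):
        if hi[j] - lo[j] == 0:
            idx[:, j] = 0

    grid = np.zeros((n_bins, n_bins), dtype=int)
    for i, j in idx:
        grid[i, j] += 1
    dense_mask = grid >= max(min_density_fraction * n, 2.0)
    if not dense_mask.any():
        return frozenset([frozenset(range(n))])
    labeled, _ = ndimage.label(dense_mask, structure=np.ones((3, 3), dtype=int))

    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = x / sd
    dense_bins = list(zip(*np.nonzero(dense_mask)))
    centroids, comp = [], []
    for bi, bj in dense_bins:
        members = [k for k in range(n) if idx[k, 0] == bi and idx[k, 1] == bj]
        centroids.append(z[members].mean(axis=0))
        comp.append(labeled[bi, bj])

    assignment = np.empty(n, dtype=int)
    for k in range(n):
        bi, bj = idx[k]
        if dense_mask[bi, bj]:
            assignment[k] = labeled[bi, bj]
        else:
            dists = [np.linalg.norm(z[k] - c) for c in centroids]
            assignment[k] = comp[int(np.argmin(dists))]
    return frozenset(
        frozenset(np.flatnonzero(assignment == lab).tolist())
        for lab in np.unique(assignment)
    )


def partition_of(labels: np.ndarray):
    return frozenset(
        frozenset(np.flatnonzero(labels == lab).tolist()) for lab in np.unique(labels)
    )


# ---------------------------------------------------------------------------
# Exact rational Fisher oracle.


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p via scipy (independent of the exact-integer path)."""
    from scipy.stats import fisher_exact

    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


def youden_oracle(values, labels, direction):
    """Naive double-loop threshold search: (best J, fewest flagged)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    distinct = np.unique(values)
    cands = [-np.inf, *((distinct[:-1] + distinct[1:]) / 2.0), np.inf]
    results = []
    for t in cands:
        flagged = values < t if direction == "below_flags_positive" else values > t
        sens = (flagged & labels).sum() / labels.sum()
        spec = (~flagged & ~labels).sum() / (~labels).sum()
        results.append((sens + spec - 1.0, int(flagged.sum()), t))
    best_j = max(r[0] for r in results)
    tied = [r for r in results if abs(r[0] - best_j) <= 1e-12]
    return min(tied, key=lambda r: r[1])  # (J, n_flagged, threshold)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
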