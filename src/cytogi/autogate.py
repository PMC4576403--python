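"""Grid-density auto-gating with per-file ordinal level profiles.

This is a density-based clustering stage in the spirit of the classic
"clustering without K" family of cytometry auto-gaters: events are binned on
an equal-width grid over each channel's observed range, bins above a density
threshold are merged into clusters by Chebyshev-adjacent connected
components, and every remaining event is attached to the nearest dense-bin
centroid so that assignment is total.  Each cluster is then summarized as a
vector of per-channel ordinal levels on a 1–4 scale (1 = negative, 2 = low,
3 = positive, 4 = high), normalized within each file so that profiles are
comparable across samples, together with the cluster's percentage of the
sample's total events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .events import EventTable

__all__ = [
    "BinnedDensity",
    "ClusterProfile",
    "SampleGating",
    "bin_events",
    "find_clusters",
    "profile_clusters",
    "normalize_levels",
    "autogate",
    "DEFAULT_N_BINS",
    "DEFAULT_MIN_DENSITY_FRACTION",
]

log = logging.getLogger(__name__)

DEFAULT_N_BINS = 12
DEFAULT_MIN_DENSITY_FRACTION = 0.001

N_LEVELS = 4


@dataclass
class ClusterProfile:
    """One auto-gated cluster: ordinal levels, raw centroid, and size."""

    cluster_id: str
    levels: dict[str, int]
    centroid: dict[str, float]
    percent_of_total: float

    def __post_init__(self) -> None:
        bad = {ch: lv for ch, lv in self.levels.items() if lv not in (1, 2, 3, 4)}
        if bad:
            raise ValueError(f"levels outside 1..4: {bad}")
        if not 0.0 <= self.percent_of_total <= 100.0:
            raise ValueError(f"percent_of_total {self.percent_of_total} outside [0, 100]")


@dataclass
class SampleGating:
    """Full auto-gating result for one sample."""

    subject_id: str | None
    visit: str | None
    clusters: list[ClusterProfile]
    n_events: int


@dataclass
class BinnedDensity:
    """Equal-width grid binning of one sample's events.

    ``coords`` lists the occupied bins (one row of per-channel bin indices
    each), ``counts`` their occupancies, and ``event_bin`` maps each event to
    its row in ``coords``.  The source events are retained so that the
    cluster-finding stage can attach sparse events and compute centroids.
    """

    events: EventTable = field(repr=False)
    coords: np.ndarray
    counts: np.ndarray
    event_bin: np.ndarray
    n_bins: int

    @property
    def n_events(self) -> int:
        return self.events.n_events


def bin_events(events: EventTable, n_bins: int = DEFAULT_N_BINS) -> BinnedDensity:
    """Assign every event to one hyper-rectangular bin.

    The grid is equal-width over each channel's observed (per-file) range.  A
    constant channel has zero range and collapses to a single bin on that
    axis, with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if events.n_events < 1:
        raise ValueError("at least one event required")

    x = events.values
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    span = hi - lo
    idx = np.zeros(x.shape, dtype=np.int64)
    for j in range(x.shape[1]):
        if span[j] == 0.0:
            log.warning(
                "channel %s is constant; collapsing to a single bin", events.channels[j]
            )
            continue
        col = np.floor((x[:, j] - lo[j]) / span[j] * n_bins).astype(np.int64)
        idx[:, j] = np.clip(col, 0, n_bins - 1)

    # Unique occupied bins via flat encoding (much faster than row-wise).
    dims = (n_bins,) * x.shape[1]
    flat = np.ravel_multi_index(tuple(idx.T), dims)
    uniq, event_bin, counts = np.unique(flat, return_inverse=True, return_counts=True)
    coords = np.stack(np.unravel_index(uniq, dims), axis=1)
    return BinnedDensity(
        events=events,
        coords=coords,
        counts=counts,
        event_bin=event_bin.ravel(),
        n_bins=n_bins,
    )


def find_clusters(
    density: BinnedDensity,
    min_density_fraction: float = DEFAULT_MIN_DENSITY_FRACTION,
) -> np.ndarray:
    """Merge dense bins into clusters and assign every event to one.

    Bins holding at least ``min_density_fraction`` of the sample's events —
    and never fewer than 2 (an isolated event is an outlier, not a cluster
    seed) — are "dense"; dense bins that are Chebyshev-adjacent (all 3^d − 1
    grid neighbors) join the same cluster.  Events in non-dense bins are attached
    to the cluster of the nearest dense-bin centroid (Euclidean distance on
    per-file z-scored channels), so percentages downstream are relative to
    the total cell population.  If no bin clears the threshold the whole
    sample becomes a single cluster, with a warning.

    Returns an integer cluster label per event.
    """
    if not 0.0 < min_density_fraction < 1.0:
        raise ValueError("min_density_fraction must be in (0, 1)")
    n = density.n_events
    threshold = max(min_density_fraction * n, 2.0)
    dense = np.flatnonzero(density.counts >= threshold)
    if dense.size == 0:
        log.warning("no bin reached density %.4g x n_events; falling back to one cluster",
                    min_density_fraction)
        return np.zeros(n, dtype=np.int64)

    dense_coords = density.coords[dense]
    if dense.size == 1:
        component = np.zeros(1, dtype=np.int64)
        n_clusters = 1
    else:
        adjacency = cdist(dense_coords, dense_coords, metric="chebyshev") <= 1.0
        n_clusters, component = connected_components(adjacency, directed=False)

    # Events already in dense bins inherit the bin's component.
    bin_to_dense = np.full(density.coords.shape[0], -1, dtype=np.int64)
    bin_to_dense[dense] = np.arange(dense.size)
    dense_of_event = bin_to_dense[density.event_bin]
    labels = np.where(dense_of_event >= 0, component[dense_of_event], -1)

    sparse_mask = labels < 0
    if np.any(sparse_mask):
        x = density.events.values
        sd = x.std(axis=0)
        sd[sd == 0.0] = 1.0
        z = x / sd
        # Dense-bin centroids = mean of the events each dense bin holds.
        in_dense = dense_of_event >= 0
        idx = dense_of_event[in_dense]
        occupancy = np.bincount(idx, minlength=dense.size).astype(float)
        centroids = np.column_stack(
            [
                np.bincount(idx, weights=z[in_dense, j], minlength=dense.size)
                for j in range(x.shape[1])
            ]
        ) / occupancy[:, None]
        _, nearest = cKDTree(centroids).query(z[sparse_mask])
        labels[sparse_mask] = component[nearest]
    return labels


def normalize_levels(centroid_value: float, channel_min: float, channel_max: float) -> int:
    """Map a cluster-centroid value to an ordinal level in {1, 2, 3, 4}.

    The per-file range ``[channel_min, channel_max]`` over cluster centroids
    is split into four equal-width intervals; the value's interval index (1 +
    floor(4·(v − min)/(max − min)), clamped to [1, 4]) is its level.  A
    zero-width range yields level 1.
    """
    if channel_min > channel_max:
        raise ValueError("channel_min must not exceed channel_max")
    if channel_max == channel_min:
        return 1
    frac = (centroid_value - channel_min) / (channel_max - channel_min)
    return int(np.clip(1 + np.floor(N_LEVELS * frac), 1, N_LEVELS))


def profile_clusters(events: EventTable, labels: np.ndarray) -> SampleGating:
    """Summarize an event-to-cluster assignment as level-vector profiles.

    Per cluster: raw-scale centroid (mean per channel), percentage of total
    events, and per-channel ordinal level from :func:`normalize_levels`
    applied against the file's centroid range.  Empty clusters are dropped
    with a warning.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != events.n_events:
        raise ValueError("one cluster label per event required")

    ids = np.unique(labels)
    sizes = {i: int(np.sum(labels == i)) for i in ids}
    centroids = np.array([events.values[labels == i].mean(axis=0) for i in ids])

    cmin = centroids.min(axis=0)
    cmax = centroids.max(axis=0)
    for j in range(len(events.channels)):
        if cmax[j] == cmin[j] and len(ids) > 1:
            log.warning(
                "cluster centroids span zero range on channel %s; all levels -> 1",
                events.channels[j],
            )

    profiles = []
    for row, i in enumerate(ids):
        if sizes[i] == 0:  # cannot happen via np.unique; guards manual input
            log.warning("dropping empty cluster %s", i)
            continue
        levels = {
            ch: normalize_levels(centroids[row, j], cmin[j], cmax[j])
            for j, ch in enumerate(events.channels)
        }
        profiles.append(
            ClusterProfile(
                cluster_id=f"C{row:02d}",
                levels=levels,
                centroid={ch: float(centroids[row, j]) for j, ch in enumerate(events.channels)},
                percent_of_total=100.0 * sizes[i] / events.n_events,
            )
        )
    return SampleGating(
        subject_id=events.subject_id,
        visit=events.visit,
        clusters=profiles,
        n_events=events.n_events,
    )


def autogate(
    events: EventTable,
    n_bins: int = DEFAULT_N_BINS,
    min_density_fraction: float = DEFAULT_MIN_DENSITY_FRACTION,
) -> SampleGating:
    """Full auto-gating of one sample: bin, cluster, and profile."""
    density = bin_events(events, n_bins=n_bins)
    labels = find_clusters(density, min_density_fraction=min_density_fraction)
    return profile_clusters(events, labels)
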