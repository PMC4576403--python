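"""In-memory container for list-mode flow-cytometry events.

One :class:`EventTable` holds the raw (uncompensated, untransformed) channel
measurements of a single sample — the content of one FCS file.  The default
panel is the seven-parameter B-cell panel used throughout this package:
forward scatter (FSC, a proxy for cell size), side scatter (SSC, a proxy for
internal granularity) and five fluorescence channels (CD19, CD21, CD23, CD5,
CD1c).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default channel panel, in acquisition order.
CHANNELS: tuple[str, ...] = ("FSC", "SSC", "CD19", "CD21", "CD23", "CD5", "CD1c")

#: Default instrument range (10-bit ADC): values live in [0, 1023].
DEFAULT_RANGE: float = 1024.0


@dataclass
class EventTable:
    """Per-event channel measurements for one sample.

    Parameters
    ----------
    values
        Array of shape ``(n_events, n_channels)`` with raw-scale measurements.
    channels
        Channel names, one per column, in order.
    ranges
        Declared instrument range per channel (the FCS ``$PnR`` keyword);
        values are expected to lie in ``[0, range)``.
    subject_id, visit
        Optional sample identity, carried through gating and joins.
    labels
        Optional per-event ground-truth population labels.  Only synthetic
        data has these; they are never used by the gating itself, only by
        validation harnesses.
    latent_gi
        Optional latent (generative) Granularity Index for synthetic samples.
    """

    values: np.ndarray
    channels: tuple[str, ...] = CHANNELS
    ranges: tuple[float, ...] | None = None
    subject_id: str | None = None
    visit: str | None = None
    labels: np.ndarray | None = field(default=None, repr=False)
    latent_gi: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (events x channels) array")
        if self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.values.shape[1]} value columns for "
                f"{len(self.channels)} declared channels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("event values must be finite")
        if self.ranges is None:
            self.ranges = tuple(DEFAULT_RANGE for _ in self.channels)
        if len(self.ranges) != len(self.channels):
            raise ValueError("one instrument range per channel required")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.values.shape[0]:
                raise ValueError("one label per event required")

    @property
    def n_events(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel(self, name: str) -> np.ndarray:
        """Return the measurement column for a named channel."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None
        return self.values[:, idx]
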