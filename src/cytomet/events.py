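"""EventMatrix — the cells × channels container every pipeline stage consumes —
plus the two standard CyTOF intensity transforms (arcsinh, max-normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import MarkerPanel

TRANSFORMS = ("raw", "arcsinh", "normalized01")


@dataclass
class EventMatrix:
    """Per-cell channel intensities with their panel and transform state.

    ``values`` has one column per panel entry, in panel order. ``sample_id``
    is either a single label for the whole matrix or a per-cell array of
    labels (after debarcoding a pooled acquisition).
    """

    values: np.ndarray
    panel: MarkerPanel
    transform: str = "raw"
    sample_id: str | np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x channels array")
        if self.values.shape[1] != len(self.panel):
            raise ValueError(
                f"column count {self.values.shape[1]} != panel size {len(self.panel)}"
            )
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValueError("event matrix contains missing/non-finite values")
        if isinstance(self.sample_id, (list, tuple, np.ndarray, pd.Series)):
            self.sample_id = np.asarray(self.sample_id)
            if len(self.sample_id) != self.n_cells:
                raise ValueError("per-cell sample_id length != cell count")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def marker(self, name: str) -> np.ndarray:
        """Column for a marker (or channel) name."""
        return self.values[:, self.panel.index_of(name)]

    def subset(self, rows) -> "EventMatrix":
        """Row subset (boolean mask or index array); panel/transform preserved."""
        rows = np.asarray(rows)
        sid = self.sample_id
        if isinstance(sid, np.ndarray):
            sid = sid[rows]
        return EventMatrix(self.values[rows], self.panel, self.transform, sid)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.panel.channel_names)
        if self.sample_id is not None:
            df.insert(0, "sample_id", self.sample_id)
        return df


def concatenate(matrices: Sequence[EventMatrix]) -> EventMatrix:
    """Stack event matrices sharing a panel and transform (pooled acquisition)."""
    if not matrices:
        raise ValueError("nothing to concatenate")
    first = matrices[0]
    for m in matrices[1:]:
        if m.panel.channel_names != first.panel.channel_names:
            raise ValueError("panels differ between matrices")
        if m.transform != first.transform:
            raise ValueError("transforms differ between matrices")
    ids = []
    for m in matrices:
        if isinstance(m.sample_id, np.ndarray):
            ids.append(m.sample_id)
        else:
            ids.append(np.repeat(m.sample_id, m.n_cells))
    return EventMatrix(
        np.vstack([m.values for m in matrices]),
        first.panel,
        first.transform,
        np.concatenate(ids) if ids else None,
    )


def arcsinh_transform(events: EventMatrix, cofactor: float = 5.0) -> EventMatrix:
    """asinh(x / cofactor), the variance-stabilizing transform for ion counts.

    Applied to every channel (barcode, viability and DNA included) so all
    downstream thresholds live on one scale. Cofactor 5 is the mass-cytometry
    convention.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if events.transform != "raw":
        raise ValueError(f"arcsinh expects raw events, got {events.transform!r}")
    return EventMatrix(
        np.arcsinh(events.values / cofactor), events.panel, "arcsinh", events.sample_id
    )


def normalize_to_max(
    events: EventMatrix,
    markers: Sequence[str],
    percentile: float | None = None,
) -> EventMatrix:
    """Divide each listed marker column by its dataset maximum.

    After normalization every listed column lies in [0, 1] with its maximum
    mapped to exactly 1; an all-zero column stays all-zero (0/0 := 0). The
    optional ``percentile`` cap (e.g. 99.9) divides by that percentile and
    clips to 1 instead — off by default to use the literal maximum.
    """
    if events.transform != "arcsinh":
        raise ValueError(f"normalization expects arcsinh events, got {events.transform!r}")
    if events.n_cells == 0:
        raise ValueError("cannot normalize an empty event matrix")
    values = events.values.copy()
    for name in markers:
        j = events.panel.index_of(name)  # KeyError for unknown marker
        col = values[:, j]
        denom = np.max(col) if percentile is None else np.percentile(col, percentile)
        if denom > 0:
            col = col / denom
            if percentile is not None:
                col = np.clip(col, None, 1.0)
        else:
            col = np.zeros_like(col)
        values[:, j] = col
    return EventMatrix(values, events.panel, "normalized01", events.sample_id)
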