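"""Combinatorial mass-tag debarcoding.

Each pooled sample carries a unique k-of-9 combination of platinum/cadmium
barcode channels. Per cell, barcode channels are rescaled to [0, 1] across
the batch (robust 1st–99th percentile min–max), the k highest channels are
taken as the candidate code, and the cell is assigned to the matching sample
when the separation — the k-th minus the (k+1)-th rescaled intensity — clears
a threshold; otherwise it is left unassigned (doublets/debris filtering).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .events import EventMatrix

log = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"


@dataclass
class BarcodeScheme:
    """Ordered barcode channels and the sample → positive-channel-set codes."""

    channels: list[str]
    codes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.channels = list(self.channels)
        self.codes = {s: frozenset(c) for s, c in self.codes.items()}
        if not self.codes:
            raise ValueError("scheme has no codes")
        sizes = {len(c) for c in self.codes.values()}
        if len(sizes) != 1:
            raise ValueError("all codes must have the same size k")
        k = sizes.pop()
        if not 1 <= k < len(self.channels):
            raise ValueError(f"code size k={k} must satisfy 1 <= k < {len(self.channels)}")
        for sample, code in self.codes.items():
            unknown = code - set(self.channels)
            if unknown:
                raise ValueError(f"code for {sample!r} uses unknown channels {sorted(unknown)}")
        if len(set(self.codes.values())) != len(self.codes):
            raise ValueError("duplicate codes in scheme")
        if len(self.codes) > math.comb(len(self.channels), k):
            raise ValueError("more codes than combinations allow")

    @property
    def k(self) -> int:
        return len(next(iter(self.codes.values())))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump({
            "channels": self.channels,
            "codes": {s: sorted(c) for s, c in self.codes.items()},
        }, sort_keys=False))
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "BarcodeScheme":
        data = yaml.safe_load(Path(path).read_text())
        return cls(data["channels"], {s: frozenset(c) for s, c in data["codes"].items()})


def default_scheme(
    sample_ids: Sequence[str],
    k: int = 3,
    channels: Sequence[str] | None = None,
) -> BarcodeScheme:
    """Channel-balanced k-combination codes for the given samples.

    Codes are chosen greedily so every barcode channel is positive in roughly
    the same number of samples — a channel that is positive in (almost) all or
    none of the pooled cells cannot be rescaled robustly. Deterministic.
    """
    if channels is None:
        from .panel import tnbc_panel
        channels = tnbc_panel().channels_of("barcode")
    channels = list(channels)
    combos = list(itertools.combinations(channels, k))
    if len(sample_ids) > len(combos):
        raise ValueError(f"{len(sample_ids)} samples exceed C({len(channels)}, {k}) codes")
    usage = {c: 0 for c in channels}
    codes: dict[str, frozenset[str]] = {}
    available = combos
    for sid in sample_ids:
        best = min(available, key=lambda combo: (sum(usage[c] for c in combo), combo))
        for c in best:
            usage[c] += 1
        codes[sid] = frozenset(best)
        available = [c for c in available if c != best]
    return BarcodeScheme(channels, codes)


@dataclass
class BarcodeCall:
    """Per-cell sample assignment and barcode separation."""

    sample: np.ndarray      # object array, sample_id or UNASSIGNED
    separation: np.ndarray  # float, k-th minus (k+1)-th rescaled intensity

    def __len__(self) -> int:
        return len(self.sample)

    @property
    def n_assigned(self) -> int:
        return int((self.sample != UNASSIGNED).sum())

    def report(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample": self.sample, "separation": self.separation})
        out = df.groupby("sample").agg(
            assigned=("sample", "size"), median_separation=("separation", "median")
        ).reset_index()
        return out.sort_values("sample").reset_index(drop=True)


def _rescale(col: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(col, [1, 99])
    if hi <= lo:
        return np.zeros_like(col)
    return np.clip((col - lo) / (hi - lo), 0.0, 1.0)


def assign_barcodes(
    events: EventMatrix,
    scheme: BarcodeScheme,
    sep_threshold: float = 0.3,
) -> BarcodeCall:
    """Assign each cell to its source sample from barcode-channel intensities.

    Requires arcsinh-transformed events. A cell is assigned iff its top-k
    rescaled barcode channels exactly match a code and the separation clears
    ``sep_threshold``; any top-k set matching no code is unassigned regardless
    of separation.
    """
    if events.transform != "arcsinh":
        raise ValueError("assign_barcodes expects arcsinh-transformed events")
    if not 0 <= sep_threshold <= 1:
        raise ValueError("sep_threshold must lie in [0, 1]")
    missing = [c for c in scheme.channels if c not in events.panel]
    if missing:
        raise KeyError(f"barcode channels missing from panel: {missing}")
    k = scheme.k

    n = events.n_cells
    sample = np.full(n, UNASSIGNED, dtype=object)
    separation = np.zeros(n)
    if n == 0:
        return BarcodeCall(sample, separation)

    cols = np.column_stack([events.marker(c) for c in scheme.channels])
    rescaled = np.column_stack([_rescale(cols[:, j]) for j in range(cols.shape[1])])

    order = np.argsort(-rescaled, axis=1, kind="stable")
    sorted_vals = -np.sort(-rescaled, axis=1)
    separation = sorted_vals[:, k - 1] - sorted_vals[:, k]

    code_lookup = {code: sid for sid, code in scheme.codes.items()}
    channels = np.array(scheme.channels, dtype=object)
    topk = order[:, :k]
    for i in range(n):
        if separation[i] < sep_threshold:
            continue
        code = frozenset(channels[topk[i]])
        sid = code_lookup.get(code)
        if sid is not None:
            sample[i] = sid
    return BarcodeCall(sample, separation)


def split_by_sample(
    events: EventMatrix, calls: BarcodeCall
) -> dict[str, EventMatrix]:
    """Partition assigned cells per sample; unassigned cells are dropped (logged)."""
    if len(calls) != events.n_cells:
        raise ValueError("barcode calls not aligned to events")
    out: dict[str, EventMatrix] = {}
    n_unassigned = int((calls.sample == UNASSIGNED).sum())
    for sid in sorted(set(calls.sample) - {UNASSIGNED}):
        rows = np.flatnonzero(calls.sample == sid)
        em = events.subset(rows)
        em.sample_id = sid
        out[sid] = em
    log.info("debarcoding: %d assigned to %d samples, %d unassigned dropped",
             events.n_cells - n_unassigned, len(out), n_unassigned)
    return out
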