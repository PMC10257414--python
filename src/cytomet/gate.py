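"""Compartment gating: singlets (DNA window), live cells (cisplatin-negative),
then PanCK+ cancer, CD45+PanCK- immune and CD90+PanCK-CD45- stromal cells.

Thresholds live on the arcsinh scale and can be fixed numbers or estimated
per marker by Otsu's method or a two-component Gaussian mixture. Double
positives are resolved by precedence cancer > immune > stromal, mirroring
sequential manual gating.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EventMatrix

log = logging.getLogger(__name__)

COMPARTMENTS = ("cancer", "immune", "stromal", "other")
LABELS = COMPARTMENTS + ("dead", "debris")

DEFAULT_THRESHOLDS = {"PanCK": 1.5, "CD45": 1.5, "CD90": 1.5, "Cisplatin": 2.5}
DEFAULT_DNA_WINDOW = (3.0, 5.8)


def otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Otsu's between-class-variance threshold on a 1-D sample."""
    values = np.asarray(values, float)
    hist, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    if total == 0:
        raise ValueError("empty sample for Otsu threshold")
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    mean_t = cum_m[-1] / total
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mean_t * cum_w - cum_m) ** 2 / (cum_w * (total - cum_w))
    between[~np.isfinite(between)] = -1
    return float(centers[int(np.argmax(between))])


def gmm2_threshold(values: np.ndarray, seed: int = 0) -> float:
    """Midpoint of the two component means of a 1-D two-Gaussian mixture."""
    from sklearn.mixture import GaussianMixture

    x = np.asarray(values, float).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=2).fit(x)
    means = np.sort(gm.means_.ravel())
    return float(means.mean())


@dataclass
class GateConfig:
    """Per-marker thresholds (arcsinh scale) and the DNA singlet window.

    ``thresholds`` maps marker name to either a number or a rule name
    ("otsu" / "gmm2") resolved on the data at gating time. Required markers:
    PanCK, CD45, CD90 and the viability marker (Cisplatin).
    """

    thresholds: dict[str, float | str] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    dna_window: tuple[float, float] = DEFAULT_DNA_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.dna_window
        if not low < high:
            raise ValueError("dna_window low must be < high")

    def resolve(self, events: EventMatrix) -> dict[str, float]:
        """Numeric thresholds, estimating rule-based entries from the data."""
        out: dict[str, float] = {}
        for marker, rule in self.thresholds.items():
            if marker not in events.panel:
                raise KeyError(f"gating marker {marker!r} not in panel")
            if isinstance(rule, str):
                col = events.marker(marker)
                if rule == "otsu":
                    out[marker] = otsu_threshold(col)
                elif rule == "gmm2":
                    out[marker] = gmm2_threshold(col, self.seed)
                else:
                    raise ValueError(f"unknown threshold rule {rule!r} for {marker!r}")
            else:
                out[marker] = float(rule)
        return out


@dataclass
class CompartmentLabels:
    """Per-cell compartment label; labels partition all input cells."""

    labels: np.ndarray  # object array over LABELS
    thresholds: dict[str, float]
    dna_window: tuple[float, float]

    def __len__(self) -> int:
        return len(self.labels)

    def mask(self, *names: str) -> np.ndarray:
        return np.isin(self.labels, names)

    @property
    def live_singlet(self) -> np.ndarray:
        return self.mask(*COMPARTMENTS)


def gate_events(events: EventMatrix, config: GateConfig | None = None) -> CompartmentLabels:
    """Label every cell as debris/dead or cancer/immune/stromal/other.

    Order of precedence: DNA outside window → debris; viability above
    threshold → dead; then PanCK+ → cancer; CD45+ (PanCK-) → immune;
    CD90+ (PanCK-/CD45-) → stromal; remainder → other.
    """
    if events.transform != "arcsinh":
        raise ValueError("gating expects arcsinh-transformed events")
    config = config or GateConfig()
    events.panel.require_gating_channels()
    for marker in ("PanCK", "CD45", "CD90"):
        if marker not in events.panel:
            raise KeyError(f"required gating marker {marker!r} missing from panel")
    n = events.n_cells
    labels = np.full(n, "other", dtype=object)
    if n == 0:
        return CompartmentLabels(labels, {}, config.dna_window)

    thr = config.resolve(events)
    viability_marker = events.panel.markers_of("viability")[0]
    if viability_marker not in thr:
        thr[viability_marker] = DEFAULT_THRESHOLDS.get("Cisplatin", 2.5)

    dna_channels = events.panel.channels_of("dna")
    dna = np.mean(np.column_stack([events.marker(c) for c in dna_channels]), axis=1)
    low, high = config.dna_window
    debris = (dna < low) | (dna > high)
    dead = ~debris & (events.marker(viability_marker) > thr[viability_marker])

    panck = events.marker("PanCK") > thr["PanCK"]
    cd45 = events.marker("CD45") > thr["CD45"]
    cd90 = events.marker("CD90") > thr["CD90"]
    live = ~debris & ~dead
    cancer = live & panck
    immune = live & ~cancer & cd45
    stromal = live & ~cancer & ~immune & cd90

    labels[debris] = "debris"
    labels[dead] = "dead"
    labels[cancer] = "cancer"
    labels[immune] = "immune"
    labels[stromal] = "stromal"
    return CompartmentLabels(labels, thr, config.dna_window)


def compartment_counts(labels: CompartmentLabels) -> pd.DataFrame:
    """Counts and live-singlet fractions per compartment."""
    live = labels.live_singlet
    n_live = int(live.sum())
    if n_live == 0:
        warnings.warn("no live singlets after gating", stacklevel=2)
        return pd.DataFrame(columns=["compartment", "n", "fraction"])
    rows = []
    for comp in COMPARTMENTS:
        n = int((labels.labels == comp).sum())
        rows.append({"compartment": comp, "n": n, "fraction": n / n_live})
    return pd.DataFrame(rows)


def gating_report(labels: CompartmentLabels) -> pd.DataFrame:
    """Full label tally including dead and debris."""
    values, counts = np.unique(labels.labels.astype(str), return_counts=True)
    return pd.DataFrame({"label": values, "n": counts}).sort_values(
        "label").reset_index(drop=True)


def compare_to_truth(labels: CompartmentLabels, truth_compartment: np.ndarray) -> pd.DataFrame:
    """Per-compartment recall/precision of gate labels against ground truth."""
    truth = np.asarray(truth_compartment, dtype=object)
    rows = []
    for comp in COMPARTMENTS:
        tp = int(((labels.labels == comp) & (truth == comp)).sum())
        fn = int(((labels.labels != comp) & (truth == comp)).sum())
        fp = int(((labels.labels == comp) & (truth != comp)).sum())
        rows.append({
            "compartment": comp,
            "recall": tp / (tp + fn) if tp + fn else np.nan,
            "precision": tp / (tp + fp) if tp + fp else np.nan,
            "n_true": tp + fn,
        })
    return pd.DataFrame(rows)
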