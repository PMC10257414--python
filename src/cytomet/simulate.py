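"""Synthetic TNBC CyTOF cohort generator.

Emulates a barcoded mass-cytometry acquisition of dissociated triple-negative
breast tumors: per patient, a mixture of PanCK+ cancer cells, CD45+ immune
cells, CD90+ stromal cells and a residual compartment, with log-normal raw
ion counts around subcluster-specific antibody means, per-marker dropout,
cisplatin-high dead cells, low-DNA debris, and 3-of-9 combinatorial mass-tag
barcodes. One latent per-patient aggressiveness factor drives three
observables at once — the Ki-67 %, nodal positivity, and the mixing weights
of the designated aggressive (CD97/pNF-kB/HLA-DR-high) and mesenchymal-leaning
(CD49f/CD44/CD90/Vimentin-high) cancer subclusters — so cluster-index
association and the negative MET-vs-index correlation are planted facts the
pipeline can be tested against.

All randomness flows from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .debarcode import BarcodeScheme, default_scheme
from .events import EventMatrix
from .fcs import write_fcs
from .panel import MarkerPanel, tnbc_panel

GATING_MARKERS = ("PanCK", "CD45", "CD90")  # abundant lineage antigens: no dropout


@dataclass(frozen=True)
class SubclusterSpec:
    """A planted cell population: antibody means over the compartment baseline.

    ``index_coupling`` scales how strongly the population's mixing weight
    grows with the patient's latent aggressiveness (0 = uncoupled).
    """

    name: str
    marker_means: dict[str, float]
    base_fraction: float
    index_coupling: float = 0.0


# -- default population profiles (raw ion-count means) -----------------------

_CANCER_BASE = {"PanCK": 90, "EpCAM": 50, "CD9": 30, "CD29": 30, "CD24": 20,
                "CD49c": 10, "Ki-67": 10, "CD45": 0.8, "CD90": 1.5}
_IMMUNE_BASE = {"CD45": 80, "PanCK": 0.6, "CD90": 1.0, "CD29": 12}
_STROMAL_BASE = {"CD90": 60, "PanCK": 0.6, "CD45": 0.8, "Vimentin": 50, "CD29": 25}
_OTHER_BASE = {"CD31": 40, "CD29": 20, "Vimentin": 25, "PanCK": 0.6,
               "CD45": 0.8, "CD90": 1.5}


def default_cancer_subclusters() -> list[SubclusterSpec]:
    return [
        SubclusterSpec("epithelial_bulk", {
            "EpCAM": 80, "CD49f": 18, "CD9": 55, "Vimentin": 3, "aSMA": 2,
            "CD44": 8, "CD97": 5, "pNF-kB": 4, "HLA-DR": 3,
        }, base_fraction=0.55, index_coupling=0.0),
        SubclusterSpec("aggressive", {
            "CD97": 70, "pNF-kB": 45, "HLA-DR": 50, "EpCAM": 55, "CD9": 35,
            "CD49f": 8, "Vimentin": 4, "aSMA": 2, "CD44": 12,
        }, base_fraction=0.25, index_coupling=1.2),
        SubclusterSpec("mesenchymal", {
            "CD49f": 60, "CD44": 55, "CD90": 30, "Vimentin": 55, "aSMA": 30,
            "EpCAM": 10, "CD9": 10, "CD97": 3, "pNF-kB": 6, "HLA-DR": 4,
        }, base_fraction=0.20, index_coupling=0.8),
    ]


def default_immune_subclusters() -> list[SubclusterSpec]:
    return [
        SubclusterSpec("t_cell", {"CD3": 45, "CD4": 25, "CD8a": 15, "CD28": 12}, 0.55),
        SubclusterSpec("myeloid", {"CD14": 40, "HLA-DR": 45, "CD38": 12}, 0.30),
        SubclusterSpec("b_nk", {"CD19": 25, "CD56": 15, "HLA-DR": 20}, 0.15),
    ]


def default_stromal_subclusters() -> list[SubclusterSpec]:
    return [
        SubclusterSpec("caf", {"aSMA": 50, "Vimentin": 70, "CD49c": 20},
                       base_fraction=0.6, index_coupling=0.5),
        SubclusterSpec("perivascular", {"CD49c": 30, "npBcatenin": 18, "aSMA": 15},
                       base_fraction=0.4),
    ]


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults emulate the source cohort at desk scale: 24 patients, 2 000 to
    20 000 cells each, compartments at roughly 10% cancer / 65% immune /
    22% stromal / 3% other, 36 analysis markers, 9 barcode channels.
    """

    n_patients: int = 24
    cells_per_patient: tuple[int, int] = (2_000, 20_000)
    compartment_fractions: tuple[float, float, float, float] = (0.10, 0.65, 0.22, 0.03)
    cancer_subclusters: list[SubclusterSpec] = field(default_factory=default_cancer_subclusters)
    immune_subclusters: list[SubclusterSpec] = field(default_factory=default_immune_subclusters)
    stromal_subclusters: list[SubclusterSpec] = field(default_factory=default_stromal_subclusters)
    noise_sigma: float = 0.30        # lognormal sigma of antibody staining
    dropout_p: float = 0.02          # per-marker non-detection probability
    dead_fraction: float = 0.05      # cisplatin-positive cells
    debris_fraction: float = 0.02    # low-DNA events
    doublet_rate: float = 0.0        # two-cell-sum events
    index_association: float = 1.0   # global scale of latent->weight coupling
    barcode_k: int = 3               # positive barcode channels per sample
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.compartment_fractions) - 1.0) > 1e-9:
            raise ValueError("compartment_fractions must sum to 1")
        lo, hi = self.cells_per_patient
        if lo > hi:
            raise ValueError("cells_per_patient min > max")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout p must be in [0, 1)")
        for group in (self.cancer_subclusters, self.immune_subclusters,
                      self.stromal_subclusters):
            if abs(sum(s.base_fraction for s in group) - 1.0) > 1e-9:
                raise ValueError("subcluster fractions within a compartment must sum to 1")

    @property
    def aggressive_subcluster(self) -> str:
        """Name of the planted index-coupled cancer subcluster."""
        return max(self.cancer_subclusters, key=lambda s: s.index_coupling).name

    def validate_markers(self, panel: MarkerPanel) -> None:
        for group in (self.cancer_subclusters, self.immune_subclusters,
                      self.stromal_subclusters):
            for spec in group:
                for m in spec.marker_means:
                    if m not in panel:
                        raise ValueError(f"subcluster {spec.name!r} names unknown marker {m!r}")

    def to_dict(self) -> dict:
        def _specs(group):
            return [{"name": s.name, "marker_means": dict(s.marker_means),
                     "base_fraction": s.base_fraction,
                     "index_coupling": s.index_coupling} for s in group]
        return {
            "n_patients": self.n_patients,
            "cells_per_patient": list(self.cells_per_patient),
            "compartment_fractions": list(self.compartment_fractions),
            "cancer_subclusters": _specs(self.cancer_subclusters),
            "immune_subclusters": _specs(self.immune_subclusters),
            "stromal_subclusters": _specs(self.stromal_subclusters),
            "noise_sigma": self.noise_sigma, "dropout_p": self.dropout_p,
            "dead_fraction": self.dead_fraction, "debris_fraction": self.debris_fraction,
            "doublet_rate": self.doublet_rate, "index_association": self.index_association,
            "barcode_k": self.barcode_k, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("cancer_subclusters", "immune_subclusters", "stromal_subclusters"):
            if key in d:
                d[key] = [SubclusterSpec(**s) for s in d[key]]
        for key in ("cells_per_patient", "compartment_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Cohort:
    """Generated cohort: per-patient raw events, clinical table, ground truth."""

    events: dict[str, EventMatrix]
    clinical: pd.DataFrame
    truth: pd.DataFrame            # per-cell: patient_id, cell_index, compartment, subcluster, barcode_sample
    scheme: BarcodeScheme
    panel: MarkerPanel
    config: CohortConfig
    files: list[Path] = field(default_factory=list)

    def truth_for(self, patient_id: str) -> pd.DataFrame:
        t = self.truth[self.truth.patient_id == patient_id]
        return t.sort_values("cell_index").reset_index(drop=True)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _lognormal_matrix(rng: np.random.Generator, means: np.ndarray, sigma) -> np.ndarray:
    """Rows of log-normal draws with E[x] = means exactly; zero mean stays zero.

    ``sigma`` is scalar or per-column; sigma 0 degenerates to the mean itself.
    """
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), means.shape[-1:])
    out = np.zeros_like(means, dtype=float)
    pos = means > 0
    if np.any(pos):
        sig = np.broadcast_to(sigma, means.shape)[pos]
        mu = np.log(means[pos]) - 0.5 * sig**2
        out[pos] = np.exp(rng.normal(mu, sig))
    return out


class _PanelLayout:
    """Precomputed column indices and mean templates for fast generation."""

    def __init__(self, panel: MarkerPanel):
        self.panel = panel
        self.n = len(panel)
        self.analysis_idx = np.array([panel.index_of(m) for m in panel.analysis_markers])
        self.barcode_idx = np.array([panel.index_of(c) for c in panel.channels_of("barcode")])
        self.viability_idx = panel.index_of(panel.channels_of("viability")[0])
        self.dna_idx = np.array([panel.index_of(c) for c in panel.channels_of("dna")])
        self.ki67_idx = panel.index_of("Ki-67") if "Ki-67" in panel else None
        droppable = [m for m in panel.analysis_markers if m not in GATING_MARKERS]
        self.dropout_idx = np.array([panel.index_of(m) for m in droppable])
        # per-channel sigma template: analysis/barcode/viability at config sigma,
        # DNA intercalator much tighter (0.12)
        self.dna_sigma = 0.12

    def means_for(self, base: dict[str, float], spec: SubclusterSpec | None) -> np.ndarray:
        means = np.full(self.n, 1.0)
        means[self.barcode_idx] = 1.5
        means[self.viability_idx] = 1.5
        means[self.dna_idx] = (280.0, 400.0)[: len(self.dna_idx)]
        for name, mu in base.items():
            means[self.panel.index_of(name)] = mu
        if spec is not None:
            for name, mu in spec.marker_means.items():
                means[self.panel.index_of(name)] = mu
        return means

    def sigma_vector(self, sigma: float) -> np.ndarray:
        s = np.full(self.n, float(sigma))
        s[self.dna_idx] = min(self.dna_sigma, sigma) if sigma < self.dna_sigma else self.dna_sigma
        return s


def generate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
    panel: MarkerPanel | None = None,
) -> Cohort:
    """Generate the synthetic cohort; optionally persist FCS/CSV/YAML to disk.

    Returns per-patient raw :class:`EventMatrix` objects (rows shuffled within
    patient), the clinical table, per-cell ground truth, and the barcode
    scheme. Fully reproducible from ``config.seed``.
    """
    panel = panel or tnbc_panel()
    config.validate_markers(panel)
    rng = np.random.default_rng(config.seed)
    layout = _PanelLayout(panel)
    sigma_vec = layout.sigma_vector(config.noise_sigma)

    patient_ids = [f"P{i+1:02d}" for i in range(config.n_patients)]
    scheme = default_scheme(patient_ids, k=config.barcode_k)

    # -- per-patient clinical observables from one latent factor -------------
    latent = rng.normal(0.0, 1.0, config.n_patients)
    ki67 = np.clip(35 + 18 * latent + rng.normal(0, 6, config.n_patients), 2, 95)
    n_excised = rng.integers(6, 25, config.n_patients)
    p_pos = _sigmoid(-1.2 + 1.1 * latent)
    n_pos = rng.binomial(n_excised, p_pos)
    clinical = pd.DataFrame({
        "patient_id": patient_ids,
        "ki67_pct": np.round(ki67, 1),
        "n_pos_nodes": n_pos,
        "n_excised_nodes": n_excised,
    })

    compartments = ("cancer", "immune", "stromal", "other")
    sub_groups = {
        "cancer": (config.cancer_subclusters, _CANCER_BASE),
        "immune": (config.immune_subclusters, _IMMUNE_BASE),
        "stromal": (config.stromal_subclusters, _STROMAL_BASE),
        "other": ([SubclusterSpec("endothelial_like", {}, 1.0)], _OTHER_BASE),
    }

    events: dict[str, EventMatrix] = {}
    truth_frames: list[pd.DataFrame] = []
    lo, hi = config.cells_per_patient

    for pi, pid in enumerate(patient_ids):
        n_cells = int(rng.integers(lo, hi + 1))
        comp_draw = rng.choice(len(compartments), size=n_cells,
                               p=np.asarray(config.compartment_fractions))
        values = np.zeros((n_cells, layout.n))
        sub_names = np.empty(n_cells, dtype=object)
        comp_names = np.array([compartments[c] for c in comp_draw], dtype=object)

        for ci, comp in enumerate(compartments):
            rows = np.flatnonzero(comp_draw == ci)
            if rows.size == 0:
                continue
            specs, base = sub_groups[comp]
            logits = np.array([
                np.log(max(s.base_fraction, 1e-12))
                + config.index_association * s.index_coupling * latent[pi]
                for s in specs
            ])
            weights = np.exp(logits - logits.max())
            weights /= weights.sum()
            pick = rng.choice(len(specs), size=rows.size, p=weights)
            for si, spec in enumerate(specs):
                sel = rows[pick == si]
                if sel.size == 0:
                    continue
                means = layout.means_for(base, spec)
                if comp == "cancer" and layout.ki67_idx is not None:
                    means[layout.ki67_idx] = 2 + 45 * (ki67[pi] / 100.0)
                values[sel] = _lognormal_matrix(
                    rng, np.tile(means, (sel.size, 1)), sigma_vec
                )
                sub_names[sel] = spec.name

        # barcode: positive channels of this sample high, rest stay low
        code = scheme.codes[pid]
        pos_cols = [layout.barcode_idx[scheme.channels.index(ch)] for ch in code]
        bc_means = np.full((n_cells, len(pos_cols)), 180.0)
        values[:, pos_cols] = _lognormal_matrix(rng, bc_means, config.noise_sigma)

        # dropout: non-detection zeroes a marker (lineage antigens exempt)
        if config.dropout_p > 0 and layout.dropout_idx.size:
            mask = rng.random((n_cells, layout.dropout_idx.size)) < config.dropout_p
            cols = values[:, layout.dropout_idx]
            cols[mask] = 0.0
            values[:, layout.dropout_idx] = cols

        # dead cells: cisplatin-high, globally attenuated antibody signal
        n_dead = int(round(config.dead_fraction * n_cells))
        dead_rows = rng.choice(n_cells, size=n_dead, replace=False) if n_dead else np.array([], int)
        if n_dead:
            values[np.ix_(dead_rows, layout.analysis_idx)] *= 0.3
            values[dead_rows, layout.viability_idx] = _lognormal_matrix(
                rng, np.full((n_dead, 1), 160.0), config.noise_sigma
            ).ravel()
            comp_names[dead_rows] = "dead"

        # debris: low DNA, near-background antibody signal
        n_debris = int(round(config.debris_fraction * n_cells))
        live_pool = np.setdiff1d(np.arange(n_cells), dead_rows)
        debris_rows = rng.choice(live_pool, size=min(n_debris, live_pool.size),
                                 replace=False) if n_debris else np.array([], int)
        if debris_rows.size:
            values[np.ix_(debris_rows, layout.analysis_idx)] *= 0.05
            values[np.ix_(debris_rows, layout.dna_idx)] = _lognormal_matrix(
                rng, np.full((debris_rows.size, len(layout.dna_idx)), 6.0),
                config.noise_sigma,
            )
            comp_names[debris_rows] = "debris"
            sub_names[debris_rows] = "debris"

        # optional doublets: sum of two events, double DNA content
        n_doub = int(round(config.doublet_rate * n_cells))
        if n_doub:
            tgt = rng.choice(n_cells, size=n_doub, replace=False)
            src = rng.integers(0, n_cells, size=n_doub)
            values[tgt] = values[tgt] + values[src]
            comp_names[tgt] = "doublet"
            sub_names[tgt] = "doublet"

        order = rng.permutation(n_cells)
        values = values[order]
        comp_names = comp_names[order]
        sub_names = sub_names[order]

        events[pid] = EventMatrix(values, panel, "raw", pid)
        truth_frames.append(pd.DataFrame({
            "patient_id": pid,
            "cell_index": np.arange(n_cells),
            "compartment": comp_names,
            "subcluster": sub_names,
            "barcode_sample": pid,
        }))

    truth = pd.concat(truth_frames, ignore_index=True)
    cohort = Cohort(events, clinical, truth, scheme, panel, config)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for pid, em in events.items():
            cohort.files.append(write_fcs(em, out_dir / f"{pid}.fcs"))
        clinical.to_csv(out_dir / "clinical.csv", index=False)
        truth.to_csv(out_dir / "ground_truth.csv", index=False)
        panel.to_yaml(out_dir / "panel.yaml")
        scheme.to_yaml(out_dir / "barcodes.yaml")
        (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return cohort


def generate_survival(
    clinical: pd.DataFrame,
    hazard_coupling: float,
    seed: int,
    baseline_hazard: float = 0.02,
    censor_horizon: float = 120.0,
) -> pd.DataFrame:
    """Attach exponential survival (time, event) to a clinical table.

    The per-patient hazard is ``baseline * exp(coupling * (index - mean))``
    where index is the Ki-67+LNR index, so positive coupling makes high-index
    patients die sooner. Censoring is independent uniform on (0, horizon].
    """
    from .scores import ki67_lnr_index

    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    rng = np.random.default_rng(seed)
    idx = ki67_lnr_index(clinical)
    index = idx["index"].to_numpy()
    rate = baseline_hazard * np.exp(hazard_coupling * (index - index.mean()))
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.uniform(0.0, censor_horizon, size=len(rate))
    out = clinical.copy()
    out["time"] = np.maximum(np.minimum(t_event, t_censor), 1e-9)
    out["event"] = (t_event <= t_censor).astype(int)
    return out
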