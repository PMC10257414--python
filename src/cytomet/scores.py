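"""Clinical and single-cell scores.

* Ki-67+LNR index — per patient, Ki-67 % normalized to the cohort maximum
  plus the lymph-node ratio (positive/excised nodes); ranges 0–2.
* MET score — per cancer cell, sum of max-normalized epithelial marker
  intensities (EpCAM + CD49f + CD9) minus the mesenchymal sum
  (Vimentin + aSMA + CD44); ranges −3 (fully mesenchymal) to +3 (fully
  epithelial); per patient, the mean over that patient's cancer cells.
* H-score — semiquantitative IHC: % positive cells (0–100) × staining
  intensity (0–3), ranging 0–300.
* hMET score — (EpCAM + CD49f) − (Vimentin + aSMA) H-scores, ranging
  −600 to 600; the histology surrogate of the MET score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .events import EventMatrix
from .panel import EPITHELIAL_MARKERS, MESENCHYMAL_MARKERS, MET_MARKERS


def ki67_lnr_index(clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-patient normalized Ki-67, LNR, and their sum (the Ki-67+LNR index).

    ``clinical`` needs columns patient_id, ki67_pct, n_pos_nodes,
    n_excised_nodes. Ki-67 is normalized to the cohort maximum, so the
    cohort-max patient has norm_ki67 = 1 and the index attains 2 only when
    that patient also has every excised node positive.
    """
    required = {"patient_id", "ki67_pct", "n_pos_nodes", "n_excised_nodes"}
    missing = required - set(clinical.columns)
    if missing:
        raise ValueError(f"clinical table missing columns {sorted(missing)}")
    if len(clinical) == 0:
        raise ValueError("empty clinical table")
    ki67 = clinical["ki67_pct"].to_numpy(float)
    pos = clinical["n_pos_nodes"].to_numpy(float)
    exc = clinical["n_excised_nodes"].to_numpy(float)
    if np.any((ki67 < 0) | (ki67 > 100)):
        raise ValueError("ki67_pct outside [0, 100]")
    if np.any(pos > exc):
        bad = clinical.loc[pos > exc, "patient_id"].iloc[0]
        raise ValueError(f"patient {bad!r} has more positive than excised nodes")
    if np.any(exc < 1):
        bad = clinical.loc[exc < 1, "patient_id"].iloc[0]
        raise ValueError(f"patient {bad!r} has no excised nodes; LNR undefined")
    ki67_max = ki67.max()
    if ki67_max <= 0:
        raise ValueError("all Ki-67 values are zero; normalization undefined")
    out = pd.DataFrame({
        "patient_id": clinical["patient_id"].to_numpy(),
        "norm_ki67": ki67 / ki67_max,
        "lnr": pos / exc,
    })
    out["index"] = out["norm_ki67"] + out["lnr"]
    return out


def met_score_cells(events: EventMatrix) -> np.ndarray:
    """Per-cell MET score on max-normalized intensities; values in [-3, 3]."""
    if events.transform != "normalized01":
        raise ValueError(
            "MET score needs max-normalized events "
            f"(transform='normalized01'), got {events.transform!r}"
        )
    missing = [m for m in MET_MARKERS if m not in events.panel]
    if missing:
        raise KeyError(f"MET markers missing from panel: {missing}")
    epi = sum(events.marker(m) for m in EPITHELIAL_MARKERS)
    mes = sum(events.marker(m) for m in MESENCHYMAL_MARKERS)
    return np.asarray(epi - mes, dtype=float)


def met_score_patient(cell_scores: np.ndarray, patient_ids) -> pd.Series:
    """Per-patient MET score: mean over that patient's cancer cells.

    Patients appearing in ``patient_ids`` with zero cells are impossible by
    construction; callers tracking a wider roster should treat absent
    patients as missing (a warning is emitted if NaNs slip through).
    """
    cell_scores = np.asarray(cell_scores, float)
    patient_ids = np.asarray(patient_ids)
    if len(cell_scores) != len(patient_ids):
        raise ValueError("cell scores and patient ids differ in length")
    if len(cell_scores) == 0:
        warnings.warn("no cancer cells; per-patient MET scores empty", stacklevel=2)
        return pd.Series(dtype=float, name="met")
    s = pd.Series(cell_scores).groupby(pd.Series(patient_ids)).mean()
    s.name = "met"
    s.index.name = "patient_id"
    return s


@dataclass(frozen=True)
class HScore:
    """Semiquantitative IHC score: % positive × intensity."""

    pct_positive: float
    intensity: float

    def __post_init__(self) -> None:
        if not 0 <= self.pct_positive <= 100:
            raise ValueError("pct_positive must lie in [0, 100]")
        if not 0 <= self.intensity <= 3:
            raise ValueError("intensity must lie in [0, 3]")

    @property
    def h(self) -> float:
        return self.pct_positive * self.intensity


def h_score(pct_positive: float, intensity: float) -> HScore:
    return HScore(float(pct_positive), float(intensity))


HMET_EPITHELIAL = ("EpCAM", "CD49f")
HMET_MESENCHYMAL = ("Vimentin", "aSMA")


def hmet_score(ihc: Mapping[str, HScore]) -> float:
    """Histology MET score: (EpCAM + CD49f) − (Vimentin + aSMA) H-scores."""
    lookup = {k.lower(): v for k, v in ihc.items()}
    missing = [m for m in HMET_EPITHELIAL + HMET_MESENCHYMAL if m.lower() not in lookup]
    if missing:
        raise KeyError(f"hMET markers missing: {missing}")
    epi = sum(lookup[m.lower()].h for m in HMET_EPITHELIAL)
    mes = sum(lookup[m.lower()].h for m in HMET_MESENCHYMAL)
    return float(epi - mes)
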