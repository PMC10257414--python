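"""Shared helpers for the numbered analysis scripts.

The cohort is the package's default synthetic study (24 patients, planted
index-coupled cancer subclusters), generated deterministically from one seed
so every script sees the same data without reading intermediate files.
"""

from pathlib import Path

import numpy as np

from cytomet.events import arcsinh_transform
from cytomet.gate import gate_events
from cytomet.simulate import CohortConfig, generate_cohort

SEED = 11
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def get_cohort():
    return generate_cohort(CohortConfig(seed=SEED))


def gate_compartment(cohort, compartment):
    """Arcsinh events of one gated compartment per patient, with aligned
    ground-truth subcluster labels."""
    out, true_sub = {}, {}
    for pid, em in cohort.events.items():
        ar = arcsinh_transform(em)
        labels = gate_events(ar)
        rows = np.flatnonzero(labels.labels == compartment)
        if rows.size == 0:
            continue
        sub = ar.subset(rows)
        sub.sample_id = pid
        out[pid] = sub
        true_sub[pid] = cohort.truth_for(pid)["subcluster"].to_numpy()[rows]
    return out, true_sub
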