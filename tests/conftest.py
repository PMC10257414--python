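import numpy as np
import pytest

from cytomet.events import arcsinh_transform
from cytomet.gate import gate_events
from cytomet.panel import tnbc_panel
from cytomet.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def panel():
    return tnbc_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured cohort: 8 patients, noise/dropout/dead/debris."""
    cfg = CohortConfig(n_patients=8, cells_per_patient=(800, 1500), seed=3)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def gated_cancer(small_cohort):
    """Arcsinh-transformed cancer cells per patient, plus their true subclusters."""
    cancer, true_sub = {}, {}
    for pid, em in small_cohort.events.items():
        ar = arcsinh_transform(em)
        labels = gate_events(ar)
        rows = np.flatnonzero(labels.labels == "cancer")
        sub = ar.subset(rows)
        sub.sample_id = pid
        cancer[pid] = sub
        true_sub[pid] = small_cohort.truth_for(pid)["subcluster"].to_numpy()[rows]
    return cancer, true_sub
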