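# cytomet

A mass-cytometry (CyTOF) analysis pipeline for dissociated solid tumors,
built around triple-negative breast cancer (TNBC): combinatorial mass-tag
debarcoding, compartment gating, SOM-based phenotype clustering with
clinical-index association, epithelial–mesenchymal (MET) scoring, and
survival statistics — together with a synthetic-cohort generator so the
whole chain is testable end to end without patient data.

## Who this is for

Cytometry bioinformaticians who want a scripted, reproducible version of the
usual FlowJo-plus-R workflow for barcoded tumor panels: pooled FCS events in,
per-cluster clinical associations and per-patient scores out, every stage a
plain Python function.

## The quantities at the core

For patient *i* with Ki-67 positivity `ki67_i` (% of tumor cells), `pos_i`
positive of `exc_i` excised lymph nodes:

```
norm_ki67_i = ki67_i / max_j ki67_j          ∈ [0, 1]
LNR_i       = pos_i / exc_i                  ∈ [0, 1]
index_i     = norm_ki67_i + LNR_i            ∈ [0, 2]      (Ki-67+LNR index)
```

Each cell inherits its patient's `(norm_ki67, LNR)`; a cluster's index is
`mean(norm_ki67) + mean(LNR)` over its member cells, so clusters enriched in
cells from clinically aggressive patients score high.

For each cancer cell, with marker intensities arcsinh-transformed and
normalized to their dataset maxima (each column in [0, 1]):

```
MET = (EpCAM + CD49f + CD9) − (Vimentin + αSMA + CD44)   ∈ [−3, +3]
```

−3 is fully mesenchymal, +3 fully epithelial, ≈0 a hybrid E/M state. The
per-patient MET score is the mean over that patient's cancer cells. The
histology analogue uses H-scores (% positive × intensity 0–3, range 0–300):
`hMET = (EpCAM + CD49f) − (Vimentin + αSMA)` ∈ [−600, 600].

Clustering follows the risk-associated-population recipe: pool gated cells
across patients at equal depth, embed with Barnes-Hut t-SNE (production
parameters: 10 000 iterations, perplexity 200, theta 0.9, eta 200), choose
the cluster number by silhouette on the map, cluster marker space with a
self-organizing map plus average-linkage metaclustering, then attach the
Ki-67+LNR index to every cluster.

## Worked example

```python
from cytomet.simulate import CohortConfig, generate_cohort
from cytomet.events import arcsinh_transform, concatenate, normalize_to_max
from cytomet.gate import gate_events
from cytomet.panel import MET_MARKERS
from cytomet.scores import ki67_lnr_index, met_score_cells, met_score_patient
from cytomet.stats import spearman
import numpy as np, pandas as pd

cohort = generate_cohort(CohortConfig(seed=11))   # 24 patients, ~273k cells
cancer = {}
for pid, em in cohort.events.items():
    ar = arcsinh_transform(em)                    # asinh(x/5)
    rows = np.flatnonzero(gate_events(ar).labels == "cancer")
    cancer[pid] = ar.subset(rows); cancer[pid].sample_id = pid

pooled = concatenate(list(cancer.values()))
norm = normalize_to_max(pooled, list(MET_MARKERS))
met = met_score_patient(met_score_cells(norm), norm.sample_id)
idx = ki67_lnr_index(cohort.clinical).set_index("patient_id")
rho, p = spearman(met, idx["index"].reindex(met.index))
print(f"rho = {rho:.3f}, p = {p:.2e}")
```

prints

```
rho = -0.882, p = 1.25e-08
```

i.e. on this synthetic cohort — whose mesenchymal-leaning cancer subcluster
is coupled to patient aggressiveness — patients with higher Ki-67+LNR index
carry cancer cells with lower (more mesenchymal/hybrid) MET scores.

The numbered scripts under `analysis/` walk the full study at cohort scale
(simulation → debarcoding/gating → clustering + index association → MET
scoring → survival), printing what each stage found and writing tables under
`results/`. On the default cohort, debarcoding assigns 100% of cells
correctly, gating recovers each compartment at recall/precision 1.0, the
cancer compartment resolves into k = 3 clusters whose highest-index cluster
coincides with the planted aggressive (CD97/pNF-κB/HLA-DR-high) subcluster
(Jaccard 0.999, permutation p = 0.005). The same stages are exposed as
subcommands of the `cytomet` CLI (`simulate`, `debarcode`, `gate`,
`cluster`, `score`, `survive`, `run-all`, `report`).

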