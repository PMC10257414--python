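# Methods

## Overview

`cytomet` implements a single-cell mass-cytometry workflow for barcoded
tumor-panel acquisitions: FCS I/O and intensity transforms, combinatorial
debarcoding, compartment gating, risk-associated population identification
(equal-depth pooling → t-SNE → cluster-number estimation → SOM
metaclustering → clinical-index association), epithelial–mesenchymal (MET)
scoring, IHC H-scores/hMET, and survival statistics. A synthetic-cohort
generator provides data with known ground truth; the package's guarantees
are therefore recovery and calibration statements about that generator, plus
exact analytic bounds of the scores.

## Intensity model and transforms

Raw values are treated as non-negative ion counts. All analysis happens on
`asinh(x / c)` with cofactor `c = 5` (the CyTOF convention; configurable).
Max-normalization divides each requested marker column by its dataset
maximum, so columns lie in [0, 1] with the maximum at exactly 1; an all-zero
column maps to zeros (0/0 := 0), since a marker with no signal carries no
information. An optional percentile cap (e.g. 99.9) is available but off by
default — the literal column maximum is the reference behavior. FCS files
are written as FCS 3.1, float32 list mode, single data segment, little
endian, `$PnN` = channel, `$PnS` = marker; the reader accepts FCS 3.0/3.1
with float or double data and matches panel channels by `$PnS` first, then
`$PnN`, case-insensitively. The TEXT delimiter is `|` because marker names
may contain `/`.

## Synthetic cohort

The generator emulates a pooled, barcoded acquisition of dissociated TNBC
tumors. Defaults (the study conditions of all recovery tests): 24 patients,
2 000–20 000 cells each; compartments at 10% PanCK+ cancer, 65% CD45+
immune, 22% CD90+ stromal, 3% other (endothelial-like); 36 analysis markers;
9 barcode channels (195/196Pt + 7 Cd isotopes); 5% cisplatin-high dead
cells, 2% low-DNA debris; optional two-cell-sum doublets (off by default).

Marker intensities are log-normal around population-specific means with
sigma = 0.30 (so E[x] equals the specified mean exactly), reflecting the
right-skewed marginals of antibody staining; DNA-intercalator channels use a
tighter sigma of 0.12 because iridium intercalation varies far less than
staining. Dropout zeroes a marker with probability 0.02 per cell to emulate
non-detection; it exempts the abundant lineage antigens (PanCK, CD45, CD90)
and the barcode/viability/DNA channels, where non-detection is rare — this
is what makes generative labels and gating rules agree on ≥ 99% of cells.
Dead cells get high viability signal and globally ×0.3-attenuated antibody
signal.

One latent per-patient aggressiveness factor `a ~ N(0,1)` drives three
observables: Ki-67 % (`35 + 18a` + noise, clipped to [2, 95]), nodal
positivity (binomial with log-odds `−1.2 + 1.1a`), and the cancer-subcluster
mixing weights (softmax of `log(base) + association × coupling × a`). The
three planted cancer populations are an epithelial bulk (EpCAM/CD9-high,
coupling 0), an aggressive CD97/pNF-κB/HLA-DR-high population (coupling
1.2), and a mesenchymal-leaning CD49f/CD44/CD90/Vimentin-high population
(coupling 0.8). High-index patients therefore carry more aggressive *and*
more mesenchymal cancer cells — which plants both the cluster-index
association and a negative per-patient MET-vs-index correlation. Survival
times are exponential with hazard `h0 · exp(coupling · (index − mean))` and
independent uniform censoring.

What the generator does **not** emulate: spillover/bead drift (inputs are
assumed compensated upstream), acquisition-time signal decay, realistic
immune sub-structure beyond three coarse populations, batch effects, and
cell–cell correlation within a tumor beyond the mixture structure. Passing
recovery tests therefore demonstrates that the pipeline identifies planted
structure of realistic magnitude under log-normal noise and dropout — not
that it is robust to uncompensated spillover or batch artifacts.

## Debarcoding

Codes are k-of-9 channel subsets (default k = 3); the default scheme picks
channel-balanced codes greedily so every barcode channel is positive in an
intermediate fraction of samples. Per cell, each barcode channel is rescaled
to [0, 1] by its 1st–99th percentile range across the batch; the top-k
channels form the candidate code, and the separation is the k-th minus the
(k+1)-th rescaled intensity. A cell is assigned iff the candidate set equals
a code and separation ≥ 0.3 (default). Assignment is invariant to common
positive rescaling of a cell's barcode channels and monotone in the
threshold. No Mahalanobis or EM refinement is attempted.

## Gating

Events are labeled in order of precedence: DNA mean outside the singlet
window (default [3.0, 5.8] on arcsinh scale) → debris; cisplatin above 2.5 →
dead; then PanCK+ → cancer, CD45+ (PanCK−) → immune, CD90+ (PanCK−/CD45−) →
stromal, remainder → other. Double positives resolve by the precedence
cancer > immune > stromal, mirroring sequential manual gating; for single
positives this reduces to the strict rules PanCK+/CD45−, CD45+/PanCK−,
CD90+/PanCK−/CD45−. Default thresholds are fixed at 1.5 (arcsinh) for the
lineage markers; Otsu and two-component-GMM estimation are available because
manual gate positions are not recoverable from a figure. The DNA window is
intentionally generous; at the default doublet rate of 0 it only removes
debris.

## Clustering and index association

Pooling drops samples below `min_cells` and downsamples every retained
sample, without replacement, to the size of the smallest retained sample.
Embedding uses scikit-learn's Barnes-Hut t-SNE (theta → `angle`, eta →
`learning_rate`); the production parameter set is iterations 10 000,
perplexity 200, theta 0.9, eta 200, while tests and the analysis scripts use
a desk-scale profile (500–1 000 iterations, perplexity 30, k estimation on a
seeded subsample of ≤ 1 500 pooled cells) chosen as this package's own
working size for cohorts of a few hundred cells per patient. Perplexity
auto-shrinks with a warning when the pool is smaller than 3× perplexity.

The cluster number is the k in [2, 8] maximizing the mean silhouette of
k-means partitions of the 2-D map, ties breaking toward smaller k
(parsimony). The criterion runs on the embedding while the clustering runs
on full marker space — deliberately hybrid: the map is where separation is
assessed, the markers are what defines the phenotype.

The SOM is a 10×10 grid of code vectors trained batch-wise for 10 epochs
with a Gaussian neighborhood whose radius shrinks linearly from
max(rows, cols)/2 to 0.5; codes are initialized from a seeded sample of the
data, and empty-neighborhood codes retain their previous value. Occupied
code vectors are agglomerated by average-linkage hierarchical clustering cut
at k metaclusters (consensus metaclustering is out of scope); cutting the
same tree at larger k refines the smaller-k partition. Requesting more
metaclusters than occupied codes is an error with a remediation hint.

Index association: every pooled cell inherits its patient's normalized
Ki-67 and LNR; a cluster's Ki-67+LNR index is the sum of the two per-cluster
means, hence in [0, 2] and equal to the patient index for single-patient
clusters. The max/min-index clusters are flagged, and a 200-permutation test
(patient → index labels shuffled) checks that the max-minus-min gap exceeds
its permutation null.

## Scores

Ki-67+LNR: Ki-67 normalized to the cohort maximum (error if all zero; error
naming the patient if excised nodes are zero) plus positive/excised node
ratio. MET: epithelial (EpCAM, CD49f, CD9) minus mesenchymal (Vimentin,
αSMA, CD44) sums of max-normalized per-cell intensities; the normalization
reference is the pooled cancer-cell dataset across all patients (a per-cell
"mean intensity" reading — normalizing per-sample means first would
contradict per-cell scoring; the scope is configurable via which events are
pooled before `normalize_to_max`). Per-patient MET is the mean over that
patient's cancer cells; patients without cancer cells are reported missing
with a warning. H-score is % positive × intensity with hard range checks;
hMET stays on the raw H-score scale (−600…600), unnormalized.

## Statistics

Spearman uses midranks and the t approximation (scipy), with an exact
permutation p available for n ≤ 10; constant vectors are an error rather
than a NaN. The paired t-test is the one-sample t on differences, two-sided,
rejecting zero-variance differences. Kaplan–Meier is the classical
product-limit estimator (S(0) = 1, right-continuous steps at event times,
censored subjects leaving the risk set after their time); the two-group
logrank uses the hypergeometric variance and a chi-square df = 1 p-value.
Both are cross-checked in the tests against brute-force risk-set/event-table
oracles and against lifelines. Stratification defaults to a median split
(value > median → high), with a fixed-threshold rule for H-score
conventions; degenerate splits warn.

## Numerical and degenerate-input choices

- 0/0 in max-normalization is 0; normalization of an empty matrix is an error.
- Silhouette ties break to smaller k; silhouette is computed on a seeded
  subsample above 5 000 cells (O(n²) memory).
- All randomness flows from explicit integer seeds (numpy `default_rng`);
  identical seeds give identical FCS payloads, subsets, embeddings, SOM
  assignments and survival draws.
- Gating of an empty matrix returns empty labels; an all-dead sample yields
  an empty live-fraction table with a warning.
- Separation-threshold 0 assigns every cell whose top-k set matches a code.

## Problem sizes

The analysis scripts and tests run the default cohort (24 patients,
2 000–20 000 cells each, ≈270 k cells total), pooling the gated cancer
compartment at ≈400 cells/patient and estimating k on a 1 500-cell t-SNE
subsample — sizes chosen as the package's desk-scale working point. The
production t-SNE parameters remain the documented defaults of `TSNEParams`
for full-scale cohorts.

## Known limitations

- No spillover compensation or bead normalization: inputs are assumed
  pre-compensated by acquisition software.
- Debarcoding has no doublet-specific model beyond the separation cutoff.
- The cluster-number criterion (silhouette on the map) is one defensible
  choice among several; with strongly overlapping populations it tends to
  merge (choose smaller k).
- Index association is descriptive — a cluster's high index is not a causal
  or even regression-adjusted statement.
- The hMET demonstration in `analysis/04` derives H-scores from the same
  synthetic intensities it compares against, so its high concordance shows
  internal consistency of the two scales, not independent validation.
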