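"""Risk-associated population identification: pool compartment cells across
patients at equal depth, embed with Barnes-Hut t-SNE, pick a cluster number by
silhouette on the map, cluster marker space with a self-organizing map plus
average-linkage metaclustering, and associate every cluster with the patients'
Ki-67+LNR index.

The cluster number is estimated on the 2-D embedding while the clustering
itself runs on the full marker space — the hybrid the workflow prescribes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .events import EventMatrix
from .scores import ki67_lnr_index

log = logging.getLogger(__name__)


@dataclass
class PooledMatrix:
    """Equal-depth pool of one compartment's cells across patients.

    ``source_rows`` keeps each pooled cell's row index within its patient's
    original event matrix, so pooled cells remain traceable to ground truth.
    """

    values: np.ndarray          # cells x markers
    marker_names: list[str]
    patient_ids: np.ndarray     # per-cell patient label
    source_rows: np.ndarray     # per-cell row index in the patient's matrix
    downsample_n: int

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


def pool_and_downsample(
    samples: Mapping[str, EventMatrix],
    min_cells: int,
    seed: int,
    markers: list[str] | None = None,
) -> PooledMatrix:
    """Pool patients' cells at equal depth.

    Patients with fewer than ``min_cells`` cells are dropped (logged); every
    retained patient contributes exactly the minimum retained cell count,
    sampled uniformly without replacement.
    """
    if len(samples) < 2:
        raise ValueError("pooling needs at least 2 samples")
    retained = {pid: em for pid, em in samples.items() if em.n_cells >= min_cells}
    dropped = sorted(set(samples) - set(retained))
    if dropped:
        log.info("pooling: dropped %d samples below %d cells: %s",
                 len(dropped), min_cells, dropped)
    if not retained:
        raise ValueError(f"all samples below min_cells={min_cells}")
    n = min(em.n_cells for em in retained.values())

    first = next(iter(retained.values()))
    if markers is None:
        markers = first.panel.analysis_markers
    cols = [first.panel.index_of(m) for m in markers]

    rng = np.random.default_rng(seed)
    blocks, pids, rows = [], [], []
    for pid in sorted(retained):
        em = retained[pid]
        take = rng.choice(em.n_cells, size=n, replace=False)
        take.sort()
        blocks.append(em.values[np.ix_(take, cols)])
        pids.append(np.repeat(pid, n))
        rows.append(take)
    return PooledMatrix(
        np.vstack(blocks), list(markers),
        np.concatenate(pids), np.concatenate(rows), n,
    )


@dataclass(frozen=True)
class TSNEParams:
    """Barnes-Hut t-SNE parameters. Defaults are the production profile
    (10 000 iterations, perplexity 200, theta 0.9, eta 200); desk-scale runs
    use :meth:`desk_scale`."""

    iterations: int = 10_000
    perplexity: float = 200.0
    theta: float = 0.9
    eta: float = 200.0
    seed: int = 0

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "TSNEParams":
        return cls(iterations=1_000, perplexity=30.0, theta=0.9, eta=200.0, seed=seed)


@dataclass
class Embedding:
    coords: np.ndarray  # cells x 2
    params: TSNEParams


def embed_tsne(pooled: PooledMatrix | np.ndarray, params: TSNEParams | None = None) -> Embedding:
    """2-D Barnes-Hut t-SNE of the pooled marker matrix; seeded, deterministic.

    Perplexity is shrunk (with a warning) when the pool is smaller than
    3 x perplexity.
    """
    params = params or TSNEParams()
    X = pooled.values if isinstance(pooled, PooledMatrix) else np.asarray(pooled, float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in embedding input")
    n = X.shape[0]
    perplexity = params.perplexity
    if n < 3 * perplexity:
        perplexity = max(2.0, (n - 1) / 3.0)
        warnings.warn(
            f"perplexity {params.perplexity} too large for {n} cells; using {perplexity:.1f}",
            stacklevel=2,
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        learning_rate=params.eta,
        angle=params.theta,
        max_iter=max(250, params.iterations),
        init="pca",
        random_state=params.seed,
        method="barnes_hut",
    )
    coords = tsne.fit_transform(X)
    return Embedding(np.asarray(coords, float), params)


def estimate_k(
    embedding: Embedding,
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
    subsample: int | None = 5_000,
) -> int:
    """Cluster-number estimate: k maximizing the mean silhouette of k-means
    partitions of the t-SNE map; ties break toward smaller k (parsimony).

    Silhouette is O(n^2); ``subsample`` caps the cells scored (seeded).
    """
    coords = embedding.coords
    lo, hi = k_range
    if not 2 <= lo <= hi <= len(coords) - 1:
        raise ValueError(f"k_range {k_range} outside [2, cells-1]")
    if np.allclose(coords, coords[0]):
        raise ValueError("degenerate embedding: all coordinates equal")
    rng = np.random.default_rng(seed)
    idx = np.arange(len(coords))
    if subsample is not None and len(coords) > subsample:
        idx = rng.choice(len(coords), size=subsample, replace=False)
    pts = coords[idx]
    best_k, best_s = lo, -np.inf
    for k in range(lo, hi + 1):
        km = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(pts)
        if len(np.unique(km.labels_)) < 2:
            continue
        s = silhouette_score(pts, km.labels_)
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    return best_k


class BatchSOM:
    """Batch self-organizing map: a rows x cols grid of code vectors trained
    with a Gaussian neighborhood whose radius shrinks linearly per epoch."""

    def __init__(self, rows: int = 10, cols: int = 10, n_epochs: int = 10, seed: int = 0):
        if rows < 1 or cols < 1:
            raise ValueError("grid must be at least 1x1")
        self.rows, self.cols, self.n_epochs, self.seed = rows, cols, n_epochs, seed
        r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        grid = np.column_stack([r.ravel(), c.ravel()]).astype(float)
        self._grid_d2 = cdist(grid, grid, "sqeuclidean")
        self.codes: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "BatchSOM":
        X = np.asarray(X, float)
        n_codes = self.rows * self.cols
        rng = np.random.default_rng(self.seed)
        init = rng.choice(len(X), size=n_codes, replace=len(X) < n_codes)
        codes = X[init].copy()
        sigma0 = max(self.rows, self.cols) / 2.0
        for epoch in range(self.n_epochs):
            sigma = max(0.5, sigma0 * (1 - epoch / self.n_epochs))
            bmu = np.argmin(cdist(X, codes, "sqeuclidean"), axis=1)
            h = np.exp(-self._grid_d2 / (2 * sigma**2))  # codes x codes
            counts = np.bincount(bmu, minlength=n_codes).astype(float)
            sums = np.zeros_like(codes)
            np.add.at(sums, bmu, X)
            num = h @ sums
            den = (h @ counts)[:, None]
            nonzero = den[:, 0] > 1e-12
            codes[nonzero] = num[nonzero] / den[nonzero]
        self.codes = codes
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.codes is None:
            raise RuntimeError("SOM not fitted")
        return np.argmin(cdist(np.asarray(X, float), self.codes, "sqeuclidean"), axis=1)


@dataclass
class ClusterAssignment:
    """Per-cell metacluster labels (1..k) with per-cluster summaries."""

    labels: np.ndarray                 # per-cell cluster id, 1..k
    patient_ids: np.ndarray
    source_rows: np.ndarray
    profiles: pd.DataFrame             # cluster x marker medians
    counts: pd.Series                  # cluster -> cell count
    composition: pd.DataFrame          # cluster x patient cell counts
    code_labels: np.ndarray            # metacluster id per SOM code (occupied)
    linkage_matrix: np.ndarray
    index: pd.Series | None = None     # cluster -> Ki-67+LNR index
    index_extremes: tuple[int, int] | None = None  # (max cluster, min cluster)

    @property
    def k(self) -> int:
        return int(self.profiles.shape[0])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "patient_id": self.patient_ids,
            "source_row": self.source_rows,
            "cluster": self.labels,
        })
        return df


def som_metacluster(
    pooled: PooledMatrix,
    grid: tuple[int, int] = (10, 10),
    k: int = 8,
    seed: int = 0,
    n_epochs: int = 10,
) -> ClusterAssignment:
    """SOM + average-linkage metaclustering of the pooled marker matrix.

    Trains the SOM on marker space, assigns every cell to its best-matching
    code, agglomerates the occupied code vectors into ``k`` metaclusters by
    average-linkage hierarchical clustering, and relabels cells accordingly.
    """
    rows, cols = grid
    if k < 2:
        raise ValueError("k must be >= 2")
    if rows * cols < k:
        raise ValueError(f"grid {grid} has fewer codes than k={k}")
    som = BatchSOM(rows, cols, n_epochs=n_epochs, seed=seed).fit(pooled.values)
    bmu = som.predict(pooled.values)
    occupied = np.unique(bmu)
    if k > len(occupied):
        raise ValueError(
            f"k={k} exceeds the {len(occupied)} occupied SOM codes; "
            "use a larger grid, more cells, or a smaller k"
        )
    Z = linkage(som.codes[occupied], method="average")
    code_meta = fcluster(Z, t=k, criterion="maxclust")  # 1..k per occupied code
    code_map = dict(zip(occupied, code_meta))
    labels = np.array([code_map[b] for b in bmu], dtype=int)

    df = pd.DataFrame(pooled.values, columns=pooled.marker_names)
    df["cluster"] = labels
    profiles = df.groupby("cluster").median()
    counts = df.groupby("cluster").size()
    counts.name = "n"
    composition = pd.crosstab(labels, pooled.patient_ids)
    composition.index.name = "cluster"
    return ClusterAssignment(
        labels=labels,
        patient_ids=pooled.patient_ids,
        source_rows=pooled.source_rows,
        profiles=profiles,
        counts=counts,
        composition=composition,
        code_labels=code_meta,
        linkage_matrix=Z,
    )


def associate_index(assign: ClusterAssignment, clinical: pd.DataFrame) -> ClusterAssignment:
    """Attach the Ki-67+LNR index to every cluster.

    Each cell inherits its patient's normalized Ki-67 and LNR; the cluster
    index is the mean normalized Ki-67 over member cells plus the mean LNR —
    in [0, 2], equal to the patient index for single-patient clusters. The
    clusters with maximal and minimal index are flagged.
    """
    idx = ki67_lnr_index(clinical).set_index("patient_id")
    pooled_patients = pd.unique(assign.patient_ids)
    missing = [p for p in pooled_patients if p not in idx.index]
    if missing:
        raise ValueError(f"patients missing from clinical table: {missing}")
    norm_ki67 = idx["norm_ki67"].reindex(assign.patient_ids).to_numpy()
    lnr = idx["lnr"].reindex(assign.patient_ids).to_numpy()
    per_cell = pd.DataFrame({
        "cluster": assign.labels, "norm_ki67": norm_ki67, "lnr": lnr,
    })
    means = per_cell.groupby("cluster").mean()
    index = means["norm_ki67"] + means["lnr"]
    index.name = "ki67_lnr_index"
    assign.index = index
    assign.index_extremes = (int(index.idxmax()), int(index.idxmin()))
    return assign


def permutation_gap_test(
    assign: ClusterAssignment,
    clinical: pd.DataFrame,
    n_perm: int = 200,
    seed: int = 0,
) -> dict:
    """Permutation-null check of the max-minus-min cluster index gap.

    Patient→(Ki-67, LNR) assignments are permuted; under no association the
    observed gap falls inside the permutation-null distribution. Returns the
    observed gap, the null gaps, and the one-sided p-value
    P(null gap >= observed).
    """
    idx = ki67_lnr_index(clinical).set_index("patient_id")
    patients = pd.unique(assign.patient_ids)
    labels = assign.labels
    rng = np.random.default_rng(seed)

    def _gap(mapping: pd.DataFrame) -> float:
        nk = mapping["norm_ki67"].reindex(assign.patient_ids).to_numpy()
        ln = mapping["lnr"].reindex(assign.patient_ids).to_numpy()
        df = pd.DataFrame({"cluster": labels, "nk": nk, "ln": ln})
        means = df.groupby("cluster").mean()
        ci = means["nk"] + means["ln"]
        return float(ci.max() - ci.min())

    observed = _gap(idx.loc[patients])
    null = np.empty(n_perm)
    base = idx.loc[patients]
    for i in range(n_perm):
        perm = base.copy()
        perm.index = rng.permutation(patients)
        null[i] = _gap(perm)
    p = (1 + (null >= observed).sum()) / (n_perm + 1)
    return {"observed_gap": observed, "null_gaps": null, "p_value": float(p)}
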