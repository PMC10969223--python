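"""CNV-based tumor-cell identification.

The caller works entirely in CNV space and proceeds in three phases:

1. **Cluster** — PCA of the cell×window CNV matrix (15 components), a
   k-nearest-neighbor graph (k=15, Euclidean, symmetrized by union), and
   Louvain community detection at resolution 2.
2. **Grow the normal set** — clusters whose normal-reference fraction
   strictly exceeds 20% become *seed* clusters; the remaining clusters are
   *unprocessed*.  The seed set is grown greedily: the unprocessed cluster
   with the highest connectivity to the seed set is absorbed while that
   connectivity is at least the minimum pairwise connectivity within the
   current seed set.  Cells in the grown set get an initial "normal" label;
   the rest are initial "tumor".
3. **Weighted bimodal call** — a Gaussian mixture fit on the initial-normal
   cells assigns each cell a negative-log-likelihood weight (shifted so the
   best-explained cell has weight 0); the weight multiplies the cell's CNV
   score, and a two-component 1-D mixture on log1p of the weighted scores
   places the final tumor threshold, with a unimodality guard.

Cells called tumor but lying in normal-condition samples are retained and
flagged ``tumor_normal``; tumor calls on non-epithelial cells are flagged
and excluded from the reported ``is_tumor`` column.
"""

from __future__ import annotations

import logging
import random
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit
from scipy.stats import norm
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import kneighbors_graph

from .cnv import CNVMatrix, cnv_score, select_reference
from .config import PipelineConfig
from .io import Dataset
from .rng import substream_seed

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterPartition",
    "SeedState",
    "reduce_cnv",
    "build_knn_graph",
    "louvain_cluster",
    "aggregate_adjacency",
    "select_seed_clusters",
    "grow_normal_set",
    "initial_decision",
    "fit_normal_gmm",
    "weighted_cnv_score",
    "bimodal_call",
    "call_tumors",
]


@dataclass
class ClusterPartition:
    labels: np.ndarray  # per-cell int, contiguous 0..n_clusters-1
    n_clusters: int

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


@dataclass
class SeedState:
    seed_set: set[int]
    unprocessed: set[int]


def reduce_cnv(cnv: CNVMatrix, n_components: int = 15,
               seed: int = 0) -> np.ndarray:
    """Project CNV profiles onto the top-variance principal components.

    Deterministic: full SVD solver with a fixed sign convention (the
    largest-magnitude loading of each component is positive).
    """
    n_cells, n_windows = cnv.values.shape
    if n_cells < n_components:
        raise ValueError(f"{n_cells} cells < {n_components} components")
    k = min(n_components, n_windows)
    if k < n_components:
        warnings.warn(
            f"only {n_windows} CNV windows; reducing components to {k}")
    pca = PCA(n_components=k, svd_solver="full", random_state=seed)
    emb = pca.fit_transform(cnv.values)
    # fix signs so the embedding does not depend on SVD sign arbitrariness
    flip = np.sign(pca.components_[np.arange(k),
                                   np.argmax(np.abs(pca.components_), axis=1)])
    flip[flip == 0] = 1.0
    return emb * flip[None, :]


def build_knn_graph(embedding: np.ndarray, k: int = 15) -> sp.csr_matrix:
    """Binary kNN adjacency, symmetrized by union; ties broken by cell index."""
    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    adj = kneighbors_graph(embedding, n_neighbors=k, mode="connectivity",
                           include_self=False)
    adj = adj.maximum(adj.T)
    adj.data[:] = 1.0
    return sp.csr_matrix(adj)


def louvain_cluster(graph: sp.csr_matrix, resolution: float = 2.0,
                    seed: int = 0) -> ClusterPartition:
    """Louvain modularity clustering of a (possibly disconnected) graph."""
    n = graph.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    coo = sp.triu(graph, k=1).tocoo()
    g = igraph.Graph(n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    igraph.set_random_number_generator(random.Random(int(seed)))
    part = g.community_multilevel(resolution=resolution)
    labels = np.asarray(part.membership, dtype=int)
    # relabel contiguously in order of first appearance (stable across runs)
    _, labels = np.unique(labels, return_inverse=True)
    return ClusterPartition(labels=labels, n_clusters=int(labels.max()) + 1)


def aggregate_adjacency(graph: sp.csr_matrix, partition: ClusterPartition,
                        normalized: bool = True) -> np.ndarray:
    """Cluster×cluster connectivity matrix.

    ``connectivity(a, b)`` is the number of edges between clusters a and b,
    divided by |a|·|b| when ``normalized`` (the default; raw counts bias
    toward large clusters).  Symmetric with zero diagonal.
    """
    k = partition.n_clusters
    labels = partition.labels
    onehot = sp.csr_matrix(
        (np.ones(len(labels)), (labels, np.arange(len(labels)))),
        shape=(k, len(labels)),
    )
    edge_counts = np.asarray((onehot @ graph @ onehot.T).todense())
    edge_counts = (edge_counts + edge_counts.T) / 2.0  # symmetrize exactly
    np.fill_diagonal(edge_counts, 0.0)
    if normalized:
        sizes = partition.sizes().astype(float)
        edge_counts /= np.outer(sizes, sizes)
    return edge_counts


def select_seed_clusters(partition: ClusterPartition,
                         reference_mask: np.ndarray,
                         fraction: float = 0.20) -> SeedState:
    """Clusters whose reference fraction strictly exceeds ``fraction`` seed
    the normal set."""
    sizes = partition.sizes()
    ref_counts = np.bincount(partition.labels[reference_mask],
                             minlength=partition.n_clusters)
    frac = ref_counts / np.maximum(sizes, 1)
    seeds = {int(c) for c in np.flatnonzero(frac > fraction)}
    if not seeds:
        raise ValueError(
            "no seed clusters: no cluster has a normal-reference fraction "
            f"> {fraction}; inspect the reference labels and clustering"
        )
    return SeedState(seed_set=seeds,
                     unprocessed=set(range(partition.n_clusters)) - seeds)


def grow_normal_set(cluster_graph: np.ndarray, state: SeedState,
                    mode: str = "max") -> set[int]:
    """Grow the seed (normal) cluster set by connectivity.

    Iteratively: every cluster's *connectivity with the seed set* is the
    ``mode`` ("max", default, or "sum") over its connectivities to
    individual seed clusters.  The threshold τ is the minimum of that
    quantity over the current seed members themselves (each member scored
    against the rest of the set; 0 with a single seed) — the most weakly
    attached normal cluster sets the bar a candidate must meet.  The
    unprocessed cluster with maximal connectivity to the seed set is
    absorbed while that connectivity is ≥ τ, recomputing both quantities
    after each absorption; otherwise growth stops.  Ties on the candidate
    score break toward the lowest cluster id, making the loop
    order-independent.
    """
    seeds = set(state.seed_set)
    unprocessed = set(state.unprocessed)
    reduce_fn = np.max if mode == "max" else np.sum
    while unprocessed:
        seed_list = sorted(seeds)
        if len(seed_list) < 2:
            tau = 0.0
        else:
            tau = min(
                float(reduce_fn(cluster_graph[s, [t for t in seed_list
                                                  if t != s]]))
                for s in seed_list
            )
        best, best_score = None, -np.inf
        for c in sorted(unprocessed):
            score = float(reduce_fn(cluster_graph[c, seed_list]))
            if score > best_score:
                best, best_score = c, score
        if best_score >= tau:
            seeds.add(best)
            unprocessed.discard(best)
        else:
            break
    return seeds


def initial_decision(partition: ClusterPartition,
                     normal_clusters: set[int]) -> np.ndarray:
    """Per-cell boolean: True where the cell's cluster is in the normal set."""
    mask = np.zeros(partition.n_clusters, dtype=bool)
    mask[sorted(normal_clusters)] = True
    return mask[partition.labels]


def fit_normal_gmm(embedding: np.ndarray, initial_normal: np.ndarray,
                   seed: int = 0, max_components: int = 5) -> GaussianMixture:
    """Diagonal-covariance Gaussian mixture fit on initial-normal cells.

    Component count minimizes BIC over 1..max_components.  A covariance
    floor of 1e-6 guards degeneracy.
    """
    X = embedding[initial_normal]
    if X.shape[0] < 50:
        raise ValueError(
            f"only {X.shape[0]} initial-normal cells; ≥ 50 required to fit "
            "the normal density model"
        )
    best, best_bic = None, np.inf
    for k in range(1, max_components + 1):
        gmm = GaussianMixture(n_components=k, covariance_type="diag",
                              reg_covar=1e-6, random_state=seed, n_init=1)
        gmm.fit(X)
        bic = gmm.bic(X)
        if bic < best_bic:
            best, best_bic = gmm, bic
    return best


def weighted_cnv_score(model: GaussianMixture, embedding: np.ndarray,
                       scores: np.ndarray, shift: bool = True) -> np.ndarray:
    """Weight CNV scores by how poorly the normal model explains each cell.

    weight(c) = −loglik(c) − min_c(−loglik), so the best-explained cell has
    weight 0 and weights are non-negative (``shift=False`` keeps raw
    −loglik).  Returns weight × cnv_score per cell.
    """
    negll = -model.score_samples(embedding)
    weight = negll - negll.min() if shift else negll
    weight = np.maximum(weight, 0.0)
    return weight * np.asarray(scores)


def _gmm_threshold_1d(x: np.ndarray, seed: int,
                      separation_sd: float = 0.5) -> float | None:
    """Two-component mixture threshold on a 1-D sample.

    Returns the smallest value where the posterior of the higher-mean
    component exceeds 0.5, or None when the fit is effectively unimodal
    (component means closer than ``separation_sd`` pooled SDs).
    """
    gmm = GaussianMixture(n_components=2, random_state=seed, reg_covar=1e-9)
    gmm.fit(x.reshape(-1, 1))
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_.ravel()
    hi = int(np.argmax(means))
    lo = 1 - hi
    pooled = np.sqrt(np.mean(sds ** 2))
    if abs(means[hi] - means[lo]) < separation_sd * pooled:
        return None
    grid = np.linspace(x.min(), x.max(), 4001)
    log_hi = np.log(weights[hi]) + norm.logpdf(grid, means[hi], sds[hi])
    log_lo = np.log(weights[lo]) + norm.logpdf(grid, means[lo], sds[lo])
    post_hi = expit(log_hi - log_lo)
    above = np.flatnonzero(post_hi > 0.5)
    if len(above) == 0:
        return None
    return float(grid[above[0]])


def _otsu_threshold(x: np.ndarray) -> float | None:
    """Otsu's between-class variance threshold (config alternative)."""
    xs = np.sort(x)
    n = len(xs)
    if xs[0] == xs[-1]:
        return None
    csum = np.cumsum(xs)
    total = csum[-1]
    idx = np.arange(1, n)
    w0 = idx / n
    w1 = 1 - w0
    mu0 = csum[:-1] / idx
    mu1 = (total - csum[:-1]) / (n - idx)
    between = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(between))
    return float((xs[k] + xs[k + 1]) / 2.0)


def bimodal_call(weighted_scores: np.ndarray, seed: int = 0,
                 method: str = "gmm") -> tuple[np.ndarray, float | None]:
    """Final tumor decision from a bimodal approximation of weighted scores.

    Fits two Gaussians to log1p of the scores and thresholds at the
    posterior crossing of the higher-mean component.  When the two
    components are effectively unimodal (means < 0.5 pooled SD apart), or
    the scores are constant, all cells are called normal and a warning is
    emitted.  Returns (is_tumor, threshold-on-original-scale-or-None).
    """
    x = np.asarray(weighted_scores, dtype=float)
    if len(x) < 2:
        raise ValueError("bimodal_call needs at least 2 cells")
    lx = np.log1p(x)
    if np.allclose(lx, lx[0]):
        warnings.warn("weighted scores are constant; calling all cells normal")
        return np.zeros(len(x), dtype=bool), None
    if method == "gmm":
        thr = _gmm_threshold_1d(lx, seed=seed)
    elif method == "otsu":
        thr = _otsu_threshold(lx)
    else:
        raise ValueError(f"unknown bimodal method {method!r}")
    if thr is None:
        warnings.warn("weighted-score distribution is effectively unimodal; "
                      "calling all cells normal")
        return np.zeros(len(x), dtype=bool), None
    return lx >= thr, float(np.expm1(thr))


def call_tumors(ds: Dataset, cnv: CNVMatrix,
                config: PipelineConfig | None = None,
                seed: int | None = None) -> pd.DataFrame:
    """Run the full caller and return one row per cell.

    Columns: ``cluster``, ``initial_normal``, ``gmm_weight``,
    ``weighted_score``, ``cnv_score``, ``is_tumor``, ``tumor_normal`` (tumor
    call in a normal-condition sample), ``nonepithelial_flag`` (score above
    threshold on a non-epithelial cell; excluded from ``is_tumor``).
    """
    cfg = config or PipelineConfig()
    root = cfg.rng_seed if seed is None else seed

    ref_mask = select_reference(ds.cells)
    emb = reduce_cnv(cnv, n_components=cfg.pca_components,
                     seed=substream_seed(root, "pca"))
    graph = build_knn_graph(emb, k=cfg.knn)
    part = louvain_cluster(graph, resolution=cfg.louvain_resolution,
                           seed=substream_seed(root, "louvain"))
    logger.info("louvain found %d clusters", part.n_clusters)
    cgraph = aggregate_adjacency(graph, part,
                                 normalized=cfg.connectivity_normalized)
    state = select_seed_clusters(part, ref_mask,
                                 fraction=cfg.seed_ref_fraction)
    normal_clusters = grow_normal_set(cgraph, state,
                                      mode=cfg.seed_connectivity_mode)
    init_normal = initial_decision(part, normal_clusters)

    feature = emb if cfg.gmm_space == "pca" else cnv.values
    model = fit_normal_gmm(feature, init_normal,
                           seed=substream_seed(root, "gmm"),
                           max_components=cfg.gmm_max_components)
    scores = cnv_score(cnv).to_numpy()
    negll = -model.score_samples(feature)
    weight = np.maximum(negll - negll.min(), 0.0)
    wscore = weight * scores
    if init_normal.all():
        # The bimodal step refines the initial decision; with no initial
        # tumor cells there is no tumor mode — the weighted scores are pure
        # noise and thresholding them would manufacture tumor calls.
        warnings.warn("initial decision marks no tumor cells; "
                      "skipping bimodal refinement")
        raw_call = np.zeros(ds.n_cells, dtype=bool)
        threshold = None
    else:
        raw_call, threshold = bimodal_call(
            wscore, seed=substream_seed(root, "bimodal"),
            method=cfg.bimodal_method)

    epithelial = (ds.cells["major_type"] == "Epithelial").to_numpy()
    is_tumor = raw_call & epithelial
    normal_cond = (ds.cells["condition"] == "Normal").to_numpy()
    out = pd.DataFrame(
        {
            "cluster": part.labels,
            "initial_normal": init_normal,
            "gmm_weight": weight,
            "cnv_score": scores,
            "weighted_score": wscore,
            "is_tumor": is_tumor,
            "tumor_normal": is_tumor & normal_cond,
            "nonepithelial_flag": raw_call & ~epithelial,
        },
        index=ds.cells.index,
    )
    out.attrs["threshold"] = threshold
    out.attrs["normal_clusters"] = sorted(normal_clusters)
    return out
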