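"""Single-cell stage: HVG selection, scaling, PCA, SNN graph, Louvain
clustering, marker detection, cell-type annotation, chromosome-level CNA
module scores and coarse cancer/immune classification.

The chain mirrors the standard graph-based single-cell workflow: lognorm ->
2000 variance-stabilized HVGs -> z-scores (clipped at +-10) -> 10 PCs ->
k=20 SNN graph with Jaccard weights (pruned below 1/15) -> Louvain at a
dataset-dependent resolution.  Cancer cells without an epithelial marker
(EPCAM-negative tumors such as GBM) are called from a chromosome-7 dosage
module score instead.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from typing import Mapping, Sequence

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix import ClusterAssignment, ExpressionMatrix, GeneAnnotation
from .scoring import log_normalize_cells, module_score
from .stats import bh_fdr, mann_whitney_u

logger = logging.getLogger(__name__)

DEFAULT_MARKER_MAP: dict[str, list[str]] = {
    "cancer": ["EPCAM"],
    "Tcell": ["CD3D", "CD8A", "CD4"],
    "Bcell": ["CD79A", "IGHM"],
    "myeloid": ["CD68", "LYZ"],
}
_TYPE_ORDER = ("cancer", "Tcell", "Bcell", "myeloid")
IMMUNE_TYPES = ("Tcell", "Bcell", "myeloid")

SNN_PRUNE = 1.0 / 15.0


@dataclass
class EmbeddingResult:
    obs_ids: list[str]
    coordinates: np.ndarray  # (n_obs, n_components)
    explained_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape[0] != len(self.obs_ids):
            raise ValueError("one coordinate row per observation required")
        if self.explained_variance is not None:
            ev = np.asarray(self.explained_variance, dtype=float)
            if np.any(np.diff(ev) > 1e-9):
                raise ValueError("explained variance must be non-increasing")
            self.explained_variance = ev


# -- feature selection and embedding --------------------------------------

def select_hvg_vst(matrix: ExpressionMatrix, n_hvg: int = 2000) -> list[str]:
    """Highly variable genes by the variance-stabilizing-transform criterion.

    A lowess trend of log10 variance on log10 mean predicts each gene's
    standard deviation; observations are standardized by the predicted sd,
    clipped at sqrt(n_obs), and genes are ranked by the variance of the
    clipped values.
    """
    if matrix.n_obs < 2:
        raise ValueError("need at least 2 observations")
    dense = matrix.dense()
    n = matrix.n_obs
    mean = dense.mean(axis=1)
    var = dense.var(axis=1, ddof=1)
    std_var = np.zeros(matrix.n_genes)
    ok = (mean > 0) & (var > 0)
    if ok.sum() >= 2:
        fitted = lowess(np.log10(var[ok]), np.log10(mean[ok]), frac=0.3,
                        return_sorted=False)
        sd_pred = np.sqrt(10.0**fitted)
        z = (dense[ok] - mean[ok, None]) / sd_pred[:, None]
        z = np.clip(z, -np.sqrt(n), np.sqrt(n))
        std_var[ok] = z.var(axis=1, ddof=1)
    order = np.argsort(-std_var, kind="stable")
    top = order[: min(n_hvg, matrix.n_genes)]
    return [matrix.gene_ids[i] for i in top]


def scale_zscore(matrix: ExpressionMatrix, genes: Sequence[str] | None = None,
                 clip: float = 10.0) -> ExpressionMatrix:
    """Per-gene z-scores clipped at +-clip; constant genes map to zero."""
    sub = matrix if genes is None else matrix.subset_genes(genes)
    dense = sub.dense()
    mean = dense.mean(axis=1, keepdims=True)
    sd = dense.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (dense - mean) / sd, 0.0)
    return sub.with_values(np.clip(z, -clip, clip), "scaled")


def pca_reduce(matrix: ExpressionMatrix, n_pcs: int = 10) -> EmbeddingResult:
    """PCA of cells in gene space; component signs fixed by making each
    component's largest-magnitude gene loading positive."""
    if n_pcs > min(matrix.n_genes, matrix.n_obs):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(n_genes, n_obs)="
            f"{min(matrix.n_genes, matrix.n_obs)}"
        )
    X = matrix.dense().T  # cells x genes
    pca = PCA(n_components=n_pcs, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(n_pcs):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1
    return EmbeddingResult(list(matrix.obs_ids), coords, pca.explained_variance_)


def tsne_embed(embedding: EmbeddingResult, seed: int = 0,
               perplexity: float = 30.0) -> EmbeddingResult:
    """2-D t-SNE of the PC coordinates — a visual aid only; layouts are not
    quantitatively interpretable and nothing downstream depends on them."""
    from sklearn.manifold import TSNE

    n = len(embedding.obs_ids)
    tsne = TSNE(n_components=2, random_state=seed,
                perplexity=min(perplexity, max(2.0, (n - 1) / 3.0)),
                init="pca")
    coords = tsne.fit_transform(embedding.coordinates)
    return EmbeddingResult(list(embedding.obs_ids), coords)


# -- graph clustering -----------------------------------------------------

def build_snn_graph(embedding: EmbeddingResult, k: int = 20) -> igraph.Graph:
    """Shared-nearest-neighbour graph: kNN in PC space (self included),
    edge weight = Jaccard overlap of neighbour sets, pruned below 1/15."""
    n = len(embedding.obs_ids)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k).fit(embedding.coordinates)
    _, idx = nn.kneighbors(embedding.coordinates)
    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix((np.ones(n * k), (rows, idx.ravel())), shape=(n, n))
    inter = adj @ adj.T  # shared-neighbour counts
    inter = sp.triu(inter.tocoo(), k=1).tocoo()
    jac = inter.data / (2 * k - inter.data)
    keep = jac >= SNN_PRUNE
    edges = list(zip(inter.row[keep].tolist(), inter.col[keep].tolist()))
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = jac[keep].tolist()
    g.vs["name"] = list(embedding.obs_ids)
    return g


def louvain_cluster(graph: igraph.Graph, resolution: float = 1.0,
                    seed: int = 0) -> ClusterAssignment:
    """Louvain modularity clustering at the given resolution; labels are
    relabelled by decreasing cluster size (0 = largest)."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    random.seed(seed)  # python-igraph draws from the stdlib RNG
    part = graph.community_multilevel(weights="weight", resolution=resolution)
    labels = np.asarray(part.membership)
    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    labels = np.array([remap[l] for l in labels])
    return ClusterAssignment(list(graph.vs["name"]), labels)


# -- marker detection -----------------------------------------------------

def _log_fc(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """ln of (mean expm1-expression + 1) ratio, rows = genes."""
    return np.log((np.expm1(a).mean(axis=1) + 1.0) / (np.expm1(b).mean(axis=1) + 1.0))


def _marker_frame(cluster, genes, lfc, p) -> pd.DataFrame:
    fdr = bh_fdr(p)
    return pd.DataFrame({
        "cluster": cluster,
        "gene_id": genes,
        "log_fc": lfc,
        "p_value": p,
        "fdr": fdr,
        "direction": np.where(lfc >= 0, "up", "down"),
    })


def _mwu_genes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-gene two-sided Mann-Whitney p; exact branch at small group sizes."""
    return np.array([
        mann_whitney_u(a[i], b[i], "two-sided").p_value for i in range(a.shape[0])
    ])


def find_all_markers(matrix: ExpressionMatrix, labels, top_n: int | None = 5,
                     min_cells: int = 3) -> pd.DataFrame:
    """One-vs-rest Mann-Whitney markers per cluster, BH-adjusted within each
    cluster's gene family, ranked by fold change; top_n rows per cluster."""
    if matrix.layer_tag != "lognorm":
        raise ValueError("find_all_markers expects a lognorm matrix")
    labels = _as_labels(labels, matrix.n_obs)
    uniq = sorted(pd.unique(labels).tolist())
    if len(uniq) < 2:
        raise ValueError("need at least two clusters")
    dense = matrix.dense()
    frames = []
    for cl in uniq:
        in_cl = labels == cl
        if in_cl.sum() < min_cells:
            logger.warning("cluster %s has <%d cells; skipped", cl, min_cells)
            continue
        a, b = dense[:, in_cl], dense[:, ~in_cl]
        lfc = _log_fc(a, b)
        p = _mwu_genes(a, b)
        frame = _marker_frame(cl, list(matrix.gene_ids), lfc, p)
        frame = frame.sort_values("log_fc", ascending=False, kind="stable")
        if top_n is not None:
            frame = frame.head(top_n)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def find_markers_pairwise(matrix: ExpressionMatrix, labels, cluster_a, cluster_b,
                          logfc_min: float = 0.25, fdr_max: float = 0.05) -> pd.DataFrame:
    """Genes differentially expressed between two clusters, gated on BOTH
    |log fold change| > logfc_min and BH-FDR < fdr_max."""
    if matrix.layer_tag != "lognorm":
        raise ValueError("find_markers_pairwise expects a lognorm matrix")
    labels = _as_labels(labels, matrix.n_obs)
    for cl in (cluster_a, cluster_b):
        if not np.any(labels == cl):
            raise ValueError(f"unknown cluster id: {cl!r}")
    dense = matrix.dense()
    a = dense[:, labels == cluster_a]
    b = dense[:, labels == cluster_b]
    lfc = _log_fc(a, b)
    p = _mwu_genes(a, b)
    frame = _marker_frame(cluster_a, list(matrix.gene_ids), lfc, p)
    frame = frame[(frame["log_fc"].abs() > logfc_min) & (frame["fdr"] < fdr_max)]
    return frame.sort_values("log_fc", ascending=False, kind="stable",
                             ignore_index=True)


def _as_labels(labels, n_obs: int) -> np.ndarray:
    if isinstance(labels, ClusterAssignment):
        labels = labels.cluster_labels
    labels = np.asarray(labels)
    if labels.shape != (n_obs,):
        raise ValueError("one label per observation required")
    return labels


# -- annotation and coarse classification ---------------------------------

def annotate_clusters(matrix: ExpressionMatrix, assignment: ClusterAssignment,
                      marker_map: Mapping[str, Sequence[str]] | None = None
                      ) -> ClusterAssignment:
    """Assign each cluster the cell type whose marker-set mean (lognorm) is
    highest in that cluster AND exceeds the all-cell mean of that marker set;
    clusters clearing neither gate stay ``unknown``."""
    if matrix.layer_tag != "lognorm":
        raise ValueError("annotate_clusters expects a lognorm matrix")
    marker_map = dict(marker_map) if marker_map is not None else DEFAULT_MARKER_MAP
    present = {
        t: [g for g in genes if g in set(matrix.gene_ids)]
        for t, genes in marker_map.items()
    }
    present = {t: g for t, g in present.items() if g}
    if not present:
        raise ValueError("no marker gene of any cell type present in matrix")
    dense = matrix.dense()
    set_means = {t: dense[[matrix.gene_index(g) for g in genes]].mean(axis=0)
                 for t, genes in present.items()}
    global_mean = {t: float(v.mean()) for t, v in set_means.items()}

    order = [t for t in _TYPE_ORDER if t in present] + [
        t for t in present if t not in _TYPE_ORDER]
    cell_type: dict[int, str] = {}
    for cl in assignment.clusters():
        cells = assignment.cells_in(cl)
        best, best_val = "unknown", -np.inf
        for t in order:
            v = float(set_means[t][cells].mean())
            if v > best_val and v > global_mean[t]:
                best, best_val = t, v
        cell_type[cl] = best
    return ClusterAssignment(list(assignment.obs_ids), assignment.cluster_labels,
                             cell_type, dict(assignment.coarse_class))


def cna_module_score(matrix: ExpressionMatrix, annotation: GeneAnnotation,
                     chromosome: str = "7", nbin: int = 24, nctrl: int = 100,
                     seed: int = 0) -> np.ndarray:
    """Copy-number-alteration proxy: module score of all genes annotated to
    one chromosome (a dosage gain raises it in the amplified cells)."""
    genes = [g for g in annotation.genes_on_chromosome(chromosome)
             if g in set(matrix.gene_ids)]
    if len(genes) < 5:
        raise ValueError(
            f"only {len(genes)} genes annotated to chromosome {chromosome!r}; need >=5"
        )
    return module_score(matrix, genes, nbin=nbin, nctrl=nctrl, seed=seed)


def _two_means_split(values: np.ndarray) -> np.ndarray:
    """1-D two-means: boolean mask of the high group (minimal within-SS split)."""
    order = np.argsort(values)
    srt = values[order]
    best_cut, best_ss = 1, np.inf
    for cut in range(1, len(srt)):
        lo, hi = srt[:cut], srt[cut:]
        ss = ((lo - lo.mean())**2).sum() + ((hi - hi.mean())**2).sum()
        if ss < best_ss:
            best_ss, best_cut = ss, cut
    high = np.zeros(len(values), dtype=bool)
    high[order[best_cut:]] = True
    return high


def classify_cancer_immune(assignment: ClusterAssignment,
                           cna_scores: np.ndarray | None = None) -> ClusterAssignment:
    """Fill the coarse cancer/immune/other class per cluster.

    Marker mode (no ``cna_scores``): cancer = clusters annotated ``cancer``.
    CNA mode: cluster-median CNA scores are split by 1-D two-means and the
    high group is called cancer.  In both modes T/B/myeloid clusters are
    immune and the remainder ``other``.
    """
    clusters = assignment.clusters()
    cell_type = dict(assignment.cell_type)
    if cna_scores is not None:
        if len(clusters) < 2:
            raise ValueError("CNA mode needs at least two clusters to split")
        cna_scores = np.asarray(cna_scores, dtype=float)
        medians = np.array([np.median(cna_scores[assignment.cells_in(c)])
                            for c in clusters])
        high = _two_means_split(medians)
        cancer_clusters = {c for c, h in zip(clusters, high) if h}
        for c in cancer_clusters:
            cell_type[c] = "cancer"
    else:
        if not cell_type:
            raise ValueError("marker mode needs cell-type annotation")
        cancer_clusters = {c for c in clusters if cell_type.get(c) == "cancer"}

    coarse = {}
    for c in clusters:
        t = cell_type.get(c, "unknown")
        if c in cancer_clusters:
            coarse[c] = "cancer"
        elif t in IMMUNE_TYPES:
            coarse[c] = "immune"
        else:
            coarse[c] = "other"
    return ClusterAssignment(list(assignment.obs_ids), assignment.cluster_labels,
                             cell_type, coarse)


# -- end-to-end estimator -------------------------------------------------

class SingleCellPipeline(ClusterMixin, BaseEstimator):
    """Counts-to-annotation single-cell pipeline as a sklearn clusterer.

    fit(X) runs lognorm -> HVG -> z-score -> PCA -> SNN -> Louvain ->
    marker annotation -> coarse cancer/immune classes (CNA mode when a
    ``gene_annotation`` is supplied).  Fitted attributes: ``labels_``,
    ``assignment_``, ``embedding_``, ``hvg_``, ``lognorm_``, ``markers_``,
    ``cna_scores_``.
    """

    def __init__(self, n_hvg: int = 2000, n_pcs: int = 10,
                 resolution: float = 0.5, knn_k: int = 20, seed: int = 0,
                 marker_map: Mapping[str, Sequence[str]] | None = None,
                 gene_annotation: GeneAnnotation | None = None,
                 cna_chromosome: str = "7",
                 module_nbin: int = 24, module_nctrl: int = 100,
                 top_n_markers: int = 5):
        self.n_hvg = n_hvg
        self.n_pcs = n_pcs
        self.resolution = resolution
        self.knn_k = knn_k
        self.seed = seed
        self.marker_map = marker_map
        self.gene_annotation = gene_annotation
        self.cna_chromosome = cna_chromosome
        self.module_nbin = module_nbin
        self.module_nctrl = module_nctrl
        self.top_n_markers = top_n_markers

    def fit(self, X: ExpressionMatrix, y=None):
        if X.layer_tag != "counts":
            raise ValueError("SingleCellPipeline expects a counts matrix")
        self.lognorm_ = log_normalize_cells(X)
        self.hvg_ = select_hvg_vst(X, n_hvg=self.n_hvg)
        scaled = scale_zscore(self.lognorm_, self.hvg_)
        self.embedding_ = pca_reduce(scaled, n_pcs=min(self.n_pcs, len(self.hvg_)))
        self.graph_ = build_snn_graph(self.embedding_, k=self.knn_k)
        assignment = louvain_cluster(self.graph_, resolution=self.resolution,
                                     seed=self.seed)
        assignment = annotate_clusters(self.lognorm_, assignment, self.marker_map)
        if self.gene_annotation is not None:
            self.cna_scores_ = cna_module_score(
                self.lognorm_, self.gene_annotation, self.cna_chromosome,
                nbin=self.module_nbin, nctrl=self.module_nctrl, seed=self.seed)
            assignment = classify_cancer_immune(assignment, self.cna_scores_)
        else:
            self.cna_scores_ = None
            assignment = classify_cancer_immune(assignment)
        self.assignment_ = assignment
        self.labels_ = assignment.cluster_labels
        self.markers_ = find_all_markers(self.lognorm_, assignment,
                                         top_n=self.top_n_markers)
        return self

    def fit_predict(self, X: ExpressionMatrix, y=None) -> np.ndarray:
        return self.fit(X).labels_
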