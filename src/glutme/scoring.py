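"""Per-observation scoring: normalization, single-sample gene-set enrichment
(ssGSEA), binned-control module scores, the composite ImmuneScore, hypoxia,
cytolytic activity, and the GLUT3/GLUT1 expression ratio (GLUTratio).

GLUTratio is the central statistic: the ratio of GLUT3 (SLC2A3, enriched in
tumor-infiltrating immune cells) to GLUT1 (SLC2A1, enriched in cancer cells)
transcript abundance, proposed as a surrogate of immune versus cancer glucose
metabolism in the tumor microenvironment.  Correlations downstream are taken
on log2 of the ratio, which symmetrizes reciprocal effects.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix import ExpressionMatrix, GeneSetCollection, ScoreTable

#: The ten immune cell types whose enrichment scores sum to the ImmuneScore.
IMMUNE_CELL_TYPES = (
    "B cells",
    "CD4+ T-cells",
    "CD8+ T-cells",
    "Dendritic cells",
    "Eosinophils",
    "Macrophages",
    "Mast cells",
    "Monocytes",
    "Neutrophils",
    "NK cells",
)


# -- normalization --------------------------------------------------------

def cpm_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million: each observation rescaled to a total of 1e6."""
    if matrix.layer_tag != "counts":
        raise ValueError(f"cpm_normalize expects counts, got {matrix.layer_tag!r}")
    dense = matrix.dense()
    totals = dense.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"observation {matrix.obs_ids[zero[0]]!r} has zero total count")
    return matrix.with_values(dense / totals * 1e6, "cpm")


def log_normalize_cells(matrix: ExpressionMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """ln(1 + scale_factor * count / cell_total), the standard lognorm layer."""
    if matrix.layer_tag != "counts":
        raise ValueError(f"log_normalize_cells expects counts, got {matrix.layer_tag!r}")
    dense = matrix.dense()
    totals = dense.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell {matrix.obs_ids[zero[0]]!r} has zero total count")
    return matrix.with_values(np.log1p(dense / totals * scale_factor), "lognorm")


# -- single-sample gene-set enrichment ------------------------------------

def ssgsea_score(values, gene_ids: Sequence[str], gene_set: Sequence[str],
                 alpha: float = 0.25) -> float:
    """Single-sample gene-set enrichment: the running-sum integral.

    Genes are ordered by decreasing expression (ties broken by gene id for
    order-independence); in-set genes accumulate weight rank^alpha (average
    ranks under ties), out-of-set genes accumulate uniformly.  The score is
    the sum over the ordered list of (weighted in-set CDF - out-of-set CDF).
    """
    values = np.asarray(values, dtype=float).ravel()
    gene_ids = [str(g) for g in gene_ids]
    if len(values) != len(gene_ids):
        raise ValueError("values and gene_ids must have equal length")
    n = len(gene_ids)
    in_set = np.array([g in set(gene_set) for g in gene_ids])
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set does not intersect the gene universe")
    if n_in == n:
        raise ValueError("gene set covers all genes; out-of-set CDF undefined")

    order = sorted(range(n), key=lambda i: (-values[i], gene_ids[i]))
    ranks = sps.rankdata(values)  # ascending, average ties
    weights = ranks**alpha

    w_in_total = weights[in_set].sum()
    n_out = n - n_in
    score = 0.0
    cdf_in = 0.0
    cdf_out = 0.0
    for i in order:
        if in_set[i]:
            cdf_in += weights[i] / w_in_total
        else:
            cdf_out += 1.0 / n_out
        score += cdf_in - cdf_out
    return float(score)


def cell_type_enrichment(matrix: ExpressionMatrix, signatures: GeneSetCollection,
                         alpha: float = 0.25) -> ScoreTable:
    """One ssGSEA score per observation per signature (cell type)."""
    dense = matrix.dense()
    table = ScoreTable(list(matrix.obs_ids))
    for name in signatures.names():
        genes = signatures[name]
        table.add(name, [
            ssgsea_score(dense[:, j], matrix.gene_ids, genes, alpha=alpha)
            for j in range(matrix.n_obs)
        ])
    return table


def immune_composite_score(table: ScoreTable) -> np.ndarray:
    """ImmuneScore: the sum of the ten immune cell-type enrichment scores.

    The component scores must already be present in ``table`` under the
    canonical names in :data:`IMMUNE_CELL_TYPES`; the sum is appended to the
    table as ``"ImmuneScore"`` and returned.
    """
    missing = [t for t in IMMUNE_CELL_TYPES if t not in table]
    if missing:
        raise ValueError(f"missing cell-type score: {missing[0]!r}")
    total = np.sum([table[t] for t in IMMUNE_CELL_TYPES], axis=0)
    if "ImmuneScore" not in table:
        table.add("ImmuneScore", total)
    return total


def hypoxia_score(matrix: ExpressionMatrix, hypoxia_set: Sequence[str],
                  alpha: float = 0.25) -> np.ndarray:
    """Per-observation ssGSEA score of a hypoxia gene signature."""
    dense = matrix.dense()
    return np.array([
        ssgsea_score(dense[:, j], matrix.gene_ids, hypoxia_set, alpha=alpha)
        for j in range(matrix.n_obs)
    ])


# -- module score ---------------------------------------------------------

def _expression_bins(means: np.ndarray, nbin: int) -> np.ndarray:
    """Equal-frequency bins of genes on the rank scale of mean expression."""
    n = means.size
    ranks = sps.rankdata(means, method="ordinal") - 1
    return (ranks * nbin // n).astype(int)


def module_score(matrix: ExpressionMatrix, gene_set: Sequence[str],
                 nbin: int = 24, nctrl: int = 100, seed: int = 0) -> np.ndarray:
    """Binned-control module score per observation.

    Genes are binned by mean expression across observations; for every gene
    of the set, ``nctrl`` control genes are drawn from its bin (with
    replacement when the bin is smaller); the score is the mean expression of
    the set minus the mean expression of all sampled controls, per
    observation.  When the universe is small, the bin count falls back to
    ``max(2, n_genes // 3)``.
    """
    genes = [g for g in gene_set if g in set(matrix.gene_ids)]
    if not genes:
        raise ValueError("gene set does not intersect the gene universe")
    dense = matrix.dense()
    n_genes = matrix.n_genes
    if n_genes < nbin * 3:
        nbin = max(2, n_genes // 3)
    means = dense.mean(axis=1)
    bins = _expression_bins(means, nbin)
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    bin_members = {b: np.flatnonzero(bins == b) for b in range(nbin)}

    rng = np.random.default_rng(seed)
    ctrl_idx: list[np.ndarray] = []
    for g in genes:
        b = bins[gene_pos[g]]
        members = bin_members[b]
        ctrl_idx.append(rng.choice(members, size=nctrl, replace=len(members) < nctrl))
    ctrl = np.concatenate(ctrl_idx)
    set_idx = [gene_pos[g] for g in genes]
    return dense[set_idx].mean(axis=0) - dense[ctrl].mean(axis=0)


# -- simple transcript-level scores ---------------------------------------

def cytolytic_score(matrix: ExpressionMatrix, gene_a: str = "GZMB",
                    gene_b: str = "PRF1", pseudocount: float = 1.0) -> np.ndarray:
    """Cytolytic activity: geometric mean of granzyme and perforin CPM.

    The gene pair is configurable because the classical construct uses GZMA
    while granzyme B is GZMB; the default follows the latter.
    """
    for g in (gene_a, gene_b):
        if g not in matrix.gene_ids:
            raise ValueError(f"gene {g!r} missing from matrix")
    a = matrix.gene_vector(gene_a) + pseudocount
    b = matrix.gene_vector(gene_b) + pseudocount
    return np.sqrt(a * b)


def glut_ratio(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> np.ndarray:
    """GLUTratio: (SLC2A3 + pc) / (SLC2A1 + pc) per observation."""
    for g in ("SLC2A3", "SLC2A1"):
        if g not in matrix.gene_ids:
            raise ValueError(f"gene {g!r} missing from matrix")
    num = matrix.gene_vector("SLC2A3") + pseudocount
    den = matrix.gene_vector("SLC2A1") + pseudocount
    return num / den


def profile_bulk(matrix: ExpressionMatrix, signatures: GeneSetCollection,
                 pseudocount: float = 1.0, alpha: float = 0.25) -> ScoreTable:
    """Full per-sample profile of a bulk cohort.

    CPM-normalizes counts, scores every signature by ssGSEA, sums the ten
    immune cell types into ImmuneScore, and appends GLUTratio (plus its log2),
    the cytolytic score and, when a ``hypoxia`` signature is supplied, the
    hypoxia ssGSEA score.
    """
    cpm = cpm_normalize(matrix) if matrix.layer_tag == "counts" else matrix
    if cpm.layer_tag != "cpm":
        raise ValueError("profile_bulk expects counts or cpm input")
    table = cell_type_enrichment(cpm, signatures, alpha=alpha)
    immune_composite_score(table)
    ratio = glut_ratio(cpm, pseudocount=pseudocount)
    table.add("GLUTratio", ratio)
    table.add("log2_GLUTratio", np.log2(ratio))
    table.add("CytolyticScore", cytolytic_score(cpm, pseudocount=pseudocount))
    return table


# -- sklearn-style estimators ----------------------------------------------

class SSGSEAScorer(TransformerMixin, BaseEstimator):
    """Transformer mapping an ExpressionMatrix to per-signature ssGSEA scores.

    Parameters
    ----------
    signatures : GeneSetCollection
        Cell-type (or pathway) signatures to score.
    alpha : float, default 0.25
        Rank-weight exponent of the running sum.
    add_immune_composite : bool, default False
        Append the ten-type ImmuneScore when all components are present.
    """

    def __init__(self, signatures: GeneSetCollection | None = None,
                 alpha: float = 0.25, add_immune_composite: bool = False):
        self.signatures = signatures
        self.alpha = alpha
        self.add_immune_composite = add_immune_composite

    def fit(self, X: ExpressionMatrix, y=None):
        if self.signatures is None or len(self.signatures) == 0:
            raise ValueError("signatures must be a non-empty GeneSetCollection")
        universe = set(X.gene_ids)
        for name in self.signatures.names():
            if not set(self.signatures[name]) & universe:
                raise ValueError(f"signature {name!r} does not intersect the gene universe")
        self.gene_universe_ = sorted(universe)
        self.n_features_in_ = X.n_genes
        return self

    def transform(self, X: ExpressionMatrix) -> ScoreTable:
        if not hasattr(self, "gene_universe_"):
            raise RuntimeError("SSGSEAScorer is not fitted")
        table = cell_type_enrichment(X, self.signatures, alpha=self.alpha)
        if self.add_immune_composite:
            immune_composite_score(table)
        return table


class ModuleScorer(TransformerMixin, BaseEstimator):
    """Transformer computing a binned-control module score for one gene set."""

    def __init__(self, gene_set: Sequence[str] = (), nbin: int = 24,
                 nctrl: int = 100, seed: int = 0):
        self.gene_set = gene_set
        self.nbin = nbin
        self.nctrl = nctrl
        self.seed = seed

    def fit(self, X: ExpressionMatrix, y=None):
        self.genes_ = [g for g in self.gene_set if g in set(X.gene_ids)]
        if not self.genes_:
            raise ValueError("gene set does not intersect the gene universe")
        self.n_features_in_ = X.n_genes
        return self

    def transform(self, X: ExpressionMatrix) -> np.ndarray:
        if not hasattr(self, "genes_"):
            raise RuntimeError("ModuleScorer is not fitted")
        return module_score(X, self.genes_, nbin=self.nbin, nctrl=self.nctrl,
                            seed=self.seed)
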