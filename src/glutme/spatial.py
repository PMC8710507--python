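"""Spatial stage: anchor-gene correlated modules and spot-level correlation.

A single spot's counts for one gene are sparse, so GLUT1 and GLUT3 are
mapped through *modules*: the top-k genes positively Pearson-correlated with
the anchor across spots (k = 50 by default), scored per spot with the
binned-control module score.  Spot-wise correlations of the module scores
with ImmuneScore and EPCAM expression quantify whether each transporter
tracks the immune-rich or the tumor region.  Scores are coordinate-free;
coordinates matter only for region-based evaluations.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import ExpressionMatrix, GeneSetCollection, ScoreTable
from .scoring import (cell_type_enrichment, cpm_normalize, immune_composite_score,
                      log_normalize_cells, module_score)
from .stats import TestResult, pearson_corr_test

logger = logging.getLogger(__name__)

ANCHOR_NAMES = {"SLC2A1": "GLUT1_module", "SLC2A3": "GLUT3_module"}


def topk_correlated_genes(matrix: ExpressionMatrix, anchor_gene: str,
                          k: int = 50) -> list[str]:
    """The k genes most positively Pearson-correlated with the anchor across
    spots (anchor excluded; only r > 0 qualify; fewer returned with a logged
    warning when fewer are positive)."""
    if matrix.n_obs < 3:
        raise ValueError("need at least 3 spots")
    anchor = matrix.gene_vector(anchor_gene)  # raises KeyError if missing
    if np.ptp(anchor) == 0:
        raise ValueError(f"anchor gene {anchor_gene!r} is constant across spots")
    dense = matrix.dense()
    a = anchor - anchor.mean()
    centered = dense - dense.mean(axis=1, keepdims=True)
    denom = np.sqrt((centered**2).sum(axis=1)) * np.sqrt((a**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, centered @ a / denom, np.nan)
    r[matrix.gene_index(anchor_gene)] = np.nan
    pos = np.flatnonzero(r > 0)
    if pos.size < k:
        logger.warning("anchor %s: only %d positively correlated genes (k=%d)",
                       anchor_gene, pos.size, k)
    top = pos[np.argsort(-r[pos], kind="stable")][:k]
    return [matrix.gene_ids[i] for i in top]


def spatial_module_scores(matrix: ExpressionMatrix,
                          anchors: Sequence[str] = ("SLC2A1", "SLC2A3"),
                          signatures: GeneSetCollection | None = None,
                          k: int = 50, nbin: int = 24, nctrl: int = 100,
                          seed: int = 0) -> ScoreTable:
    """Per-spot score table: one module score per anchor, the ten-type
    ImmuneScore, and raw EPCAM lognorm expression."""
    if matrix.layer_tag == "counts":
        lognorm = log_normalize_cells(matrix)
        cpm = cpm_normalize(matrix)
    else:
        raise ValueError("spatial_module_scores expects a counts matrix")

    table = ScoreTable(list(matrix.obs_ids))
    for anchor in anchors:
        genes = topk_correlated_genes(lognorm, anchor, k=k)
        name = ANCHOR_NAMES.get(anchor, f"{anchor}_module")
        table.add(name, module_score(lognorm, genes, nbin=nbin, nctrl=nctrl,
                                     seed=seed))
    if signatures is not None:
        enr = cell_type_enrichment(cpm, signatures)
        immune_composite_score(enr)
        table.add("ImmuneScore", enr["ImmuneScore"])
    if "EPCAM" in lognorm.gene_ids:
        table.add("EPCAM", lognorm.gene_vector("EPCAM"))
    return table


def spot_correlation(table: ScoreTable, x: str, y: str) -> TestResult:
    """Pearson correlation of two score columns across spots."""
    return pearson_corr_test(table[x], table[y])


class SpatialModuleMapper(BaseEstimator):
    """Anchor-module mapper over a spatial section, sklearn-style.

    fit(X) learns the top-k correlated gene list per anchor and computes the
    per-spot score table; fitted attributes ``topk_genes_`` (dict anchor ->
    gene list) and ``scores_`` (ScoreTable).
    """

    def __init__(self, anchors: Sequence[str] = ("SLC2A1", "SLC2A3"),
                 signatures: GeneSetCollection | None = None, k: int = 50,
                 nbin: int = 24, nctrl: int = 100, seed: int = 0):
        self.anchors = anchors
        self.signatures = signatures
        self.k = k
        self.nbin = nbin
        self.nctrl = nctrl
        self.seed = seed

    def fit(self, X: ExpressionMatrix, y=None):
        lognorm = log_normalize_cells(X)
        self.topk_genes_ = {a: topk_correlated_genes(lognorm, a, k=self.k)
                            for a in self.anchors}
        self.scores_ = spatial_module_scores(
            X, anchors=self.anchors, signatures=self.signatures, k=self.k,
            nbin=self.nbin, nctrl=self.nctrl, seed=self.seed)
        return self

    def transform(self, X: ExpressionMatrix) -> pd.DataFrame:
        if not hasattr(self, "scores_"):
            raise RuntimeError("SpatialModuleMapper is not fitted")
        return self.scores_.to_frame()

    def correlation(self, x: str, y: str) -> TestResult:
        return spot_correlation(self.scores_, x, y)
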