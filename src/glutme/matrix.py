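"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`ExpressionMatrix`, a gene-by-observation
numeric matrix with identifier sidecars and a ``layer_tag`` recording which
normalization has been applied (``counts``, ``cpm``, ``lognorm`` or
``scaled``).  Genes are rows everywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

LAYER_TAGS = ("counts", "cpm", "lognorm", "scaled")


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} identifier: {dup!r}")
    return ids


@dataclass
class ExpressionMatrix:
    """Gene-by-observation expression matrix.

    Parameters
    ----------
    values
        ``(n_genes, n_obs)`` dense array or scipy sparse matrix.
    gene_ids, obs_ids
        Ordered, unique identifiers for rows and columns.
    layer_tag
        One of ``counts``, ``cpm``, ``lognorm``, ``scaled``.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    obs_ids: list[str]
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.obs_ids = _check_unique(self.obs_ids, "observation")
        if self.layer_tag not in LAYER_TAGS:
            raise ValueError(
                f"layer_tag must be one of {LAYER_TAGS}, got {self.layer_tag!r}"
            )
        if not sp.issparse(self.values):
            self.values = np.asarray(self.values, dtype=float)
            if self.values.ndim != 2:
                raise ValueError("values must be a 2-D matrix")
        shape = self.values.shape
        if shape != (len(self.gene_ids), len(self.obs_ids)):
            raise ValueError(
                f"matrix shape {shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.obs_ids)} observations"
            )
        if self.layer_tag == "counts":
            vmin = self.values.min() if shape[0] and shape[1] else 0.0
            if vmin < 0:
                raise ValueError("counts layer must be non-negative")

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    def dense(self) -> np.ndarray:
        """Return values as a dense float ndarray (copy-free when possible)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present in matrix") from None

    def gene_vector(self, gene: str) -> np.ndarray:
        """Per-observation values for one gene."""
        i = self.gene_index(gene)
        if sp.issparse(self.values):
            return np.asarray(self.values[i].todense()).ravel()
        return self.values[i]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in genes]
        vals = self.values[idx] if not sp.issparse(self.values) else self.values[idx, :]
        return ExpressionMatrix(vals, [self.gene_ids[i] for i in idx],
                                list(self.obs_ids), self.layer_tag)

    def subset_obs(self, obs: Sequence[str]) -> "ExpressionMatrix":
        pos = {o: j for j, o in enumerate(self.obs_ids)}
        idx = [pos[o] for o in obs]
        vals = self.values[:, idx]
        return ExpressionMatrix(vals, list(self.gene_ids), [self.obs_ids[i] for i in idx],
                                self.layer_tag)

    def with_values(self, values, layer_tag: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values, list(self.gene_ids), list(self.obs_ids), layer_tag)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.gene_ids, columns=self.obs_ids)


@dataclass
class ScoreTable:
    """Observation-by-score table (enrichment scores, module scores, ratios)."""

    obs_ids: list[str]
    scores: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.obs_ids = _check_unique(self.obs_ids, "observation")
        for name, vec in list(self.scores.items()):
            self.scores[name] = self._coerce(name, vec)

    def _coerce(self, name: str, vec) -> np.ndarray:
        arr = np.asarray(vec, dtype=float)
        if arr.shape != (len(self.obs_ids),):
            raise ValueError(
                f"score {name!r} has length {arr.size}, expected {len(self.obs_ids)}"
            )
        return arr

    def add(self, name: str, vec) -> None:
        if name in self.scores:
            raise ValueError(f"score name {name!r} already present")
        self.scores[name] = self._coerce(name, vec)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.scores[name]
        except KeyError:
            raise KeyError(f"score {name!r} not in table") from None

    def __contains__(self, name: str) -> bool:
        return name in self.scores

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.obs_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT-shaped)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")
            self.descriptions.setdefault(name, "")

    def add(self, name: str, genes: Sequence[str], description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene set name: {name!r}")
        genes = list(genes)
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {name!r} contains duplicate genes")
        self.sets[name] = genes
        self.descriptions[name] = description

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class GeneAnnotation:
    """Gene -> chromosome (+ optional planted cell-type program) table."""

    table: pd.DataFrame  # index: gene_id; columns: chromosome, is_marker_of

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("gene_id not unique in annotation table")
        for col in ("chromosome", "is_marker_of"):
            if col not in self.table.columns:
                raise ValueError(f"annotation table missing column {col!r}")

    def genes_on_chromosome(self, chromosome: str) -> list[str]:
        mask = self.table["chromosome"].astype(str) == str(chromosome)
        return list(self.table.index[mask])

    def genes_of_program(self, programs: Sequence[str]) -> list[str]:
        mask = self.table["is_marker_of"].isin(list(programs))
        return list(self.table.index[mask])


@dataclass
class SyntheticTruth:
    """Planted parameters of a simulated dataset; ground truth for recovery tests."""

    seed: int
    immune_fraction: Mapping[str, float] | None = None
    cell_type_labels: Mapping[str, str] | None = None
    amplified_flags: Mapping[str, bool] | None = None
    effect_sizes: dict[str, float] = field(default_factory=dict)
    library_sizes: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.immune_fraction is not None:
            bad = {k: v for k, v in self.immune_fraction.items() if not 0.0 <= v <= 1.0}
            if bad:
                raise ValueError(f"immune_fraction outside [0,1]: {bad}")


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels plus per-cluster cell-type and coarse class."""

    obs_ids: list[str]
    cluster_labels: np.ndarray  # int >= 0, one per cell
    cell_type: dict[int, str] = field(default_factory=dict)
    coarse_class: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.obs_ids = _check_unique(self.obs_ids, "observation")
        self.cluster_labels = np.asarray(self.cluster_labels, dtype=int)
        if self.cluster_labels.shape != (len(self.obs_ids),):
            raise ValueError("one cluster label per cell required")
        if self.cluster_labels.size and self.cluster_labels.min() < 0:
            raise ValueError("cluster labels must be >= 0")

    def clusters(self) -> list[int]:
        return sorted(set(self.cluster_labels.tolist()))

    def cells_in(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.cluster_labels == cluster)

    def cell_coarse_classes(self) -> np.ndarray:
        """Per-cell coarse class derived from per-cluster assignments."""
        return np.array([self.coarse_class.get(c, "other") for c in self.cluster_labels])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": self.cluster_labels,
                "cell_type": [self.cell_type.get(c, "unknown") for c in self.cluster_labels],
                "coarse_class": [self.coarse_class.get(c, "other") for c in self.cluster_labels],
            },
            index=self.obs_ids,
        )
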