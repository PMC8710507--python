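"""Synthetic bulk, single-cell and spatial transcriptomes with planted truth.

Every generator plants the immunometabolic structure the pipeline is built to
recover: SLC2A3 (GLUT3), granzyme/perforin and the immune cell-type
signatures ride the immune compartment, SLC2A1 (GLUT1), EPCAM and the
hypoxia signature ride the cancer compartment, and an optional chromosome-7
dosage gain marks cancer cells.  Counts are gamma-Poisson (negative
binomial) with a single dispersion parameter; generators are pure functions
of their arguments including the seed.

A fixed reserved gene roster occupies the first rows of every matrix so the
planted truth is auditable; remaining genes are i.i.d. background, fifty of
which are annotated to chromosome "7" (all others to "1").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, GeneAnnotation, GeneSetCollection, SyntheticTruth
from .scoring import IMMUNE_CELL_TYPES

# -- gene roster ----------------------------------------------------------

_SIG_SLUGS = {
    "B cells": "BC",
    "CD4+ T-cells": "CD4T",
    "CD8+ T-cells": "CD8T",
    "Dendritic cells": "DC",
    "Eosinophils": "EOS",
    "Macrophages": "MAC",
    "Mast cells": "MAST",
    "Monocytes": "MONO",
    "Neutrophils": "NEU",
    "NK cells": "NK",
    "hypoxia": "HYP",
    "glycolysis": "GLY",
    "OXPHOS": "OXP",
}

#: which single-cell compartment carries each immune signature
SIGNATURE_COMPARTMENT = {
    "B cells": "Bcell",
    "CD4+ T-cells": "Tcell",
    "CD8+ T-cells": "Tcell",
    "NK cells": "Tcell",
    "Dendritic cells": "myeloid",
    "Eosinophils": "myeloid",
    "Macrophages": "myeloid",
    "Mast cells": "myeloid",
    "Monocytes": "myeloid",
    "Neutrophils": "myeloid",
}

CELL_TYPES = ("cancer", "Tcell", "Bcell", "myeloid")

TYPE_MARKERS = {
    "cancer": ["EPCAM"],
    "Tcell": ["CD3D", "CD8A", "CD4"],
    "Bcell": ["CD79A", "IGHM"],
    "myeloid": ["CD68", "LYZ"],
}

_SPECIAL_GENES = ["SLC2A1", "SLC2A3", "EPCAM", "GZMB", "PRF1", "GZMA",
                  "CD3D", "CD8A", "CD4", "CD79A", "IGHM", "CD68", "LYZ"]

N_CHR7_BACKGROUND = 50


def builtin_signature_collection() -> GeneSetCollection:
    """Toy 5-gene signatures for the ten immune cell types plus hypoxia,
    glycolysis and OXPHOS; the same genes the generators plant."""
    coll = GeneSetCollection()
    for name, slug in _SIG_SLUGS.items():
        genes = [f"{slug}.SIG{i}" for i in range(1, 6)]
        coll.add(name, genes, "synthetic 5-gene signature")
    return coll


def _gene_roster() -> tuple[list[str], GeneSetCollection]:
    coll = builtin_signature_collection()
    genes = list(_SPECIAL_GENES)
    for name in coll.names():
        genes.extend(coll[name])
    return genes, coll


_ROSTER, _SIGNATURES = _gene_roster()
MIN_GENES = len(_ROSTER) + N_CHR7_BACKGROUND  # roster + chr7-annotated background


def _gene_table(n_genes: int) -> tuple[list[str], GeneAnnotation]:
    """Full gene list (roster first, then background) with annotation."""
    if n_genes < MIN_GENES:
        raise ValueError(
            f"n_genes={n_genes} too small to host the reserved gene roster; "
            f"minimum is {MIN_GENES}"
        )
    background = [f"BG{i:04d}" for i in range(n_genes - len(_ROSTER))]
    genes = _ROSTER + background

    chromosome = {g: "1" for g in genes}
    for g in background[:N_CHR7_BACKGROUND]:
        chromosome[g] = "7"

    marker_of: dict[str, object] = {g: None for g in genes}
    marker_of["SLC2A1"] = "cancer"
    marker_of["EPCAM"] = "cancer"
    marker_of["SLC2A3"] = "immune"
    for g in ("GZMB", "PRF1", "GZMA"):
        marker_of[g] = "immune"
    for ctype, mks in TYPE_MARKERS.items():
        for g in mks:
            if g != "EPCAM":
                marker_of[g] = ctype
    for name, comp in SIGNATURE_COMPARTMENT.items():
        for g in _SIGNATURES[name]:
            marker_of[g] = comp
    for g in _SIGNATURES["hypoxia"]:
        marker_of[g] = "cancer"

    table = pd.DataFrame(
        {"chromosome": [chromosome[g] for g in genes],
         "is_marker_of": [marker_of[g] for g in genes]},
        index=pd.Index(genes, name="gene_id"),
    )
    return genes, GeneAnnotation(table)


IMMUNE_PROGRAMS = ("Tcell", "Bcell", "myeloid", "immune")


def _base_means(rng: np.random.Generator, n_genes: int) -> np.ndarray:
    """Baseline per-gene mean expression: fixed for roster genes, lognormal
    background so expression bins are non-degenerate."""
    base = np.empty(n_genes)
    base[: len(_ROSTER)] = 20.0
    base[len(_ROSTER):] = rng.lognormal(mean=2.0, sigma=1.0, size=n_genes - len(_ROSTER))
    return base


def _immune_cancer_profiles(base: np.ndarray, genes: list[str],
                            annotation: GeneAnnotation,
                            effect: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean profiles of the cancer and (pooled) immune compartments: every
    immune-program gene gets the full fold change in the immune profile, every
    cancer-program gene (SLC2A1, EPCAM, hypoxia) the full fold change in the
    cancer profile."""
    marker_of = annotation.table["is_marker_of"]
    cancer = base.copy()
    immune = base.copy()
    for i, g in enumerate(genes):
        prog = marker_of.loc[g]
        if prog == "cancer":
            cancer[i] *= effect
        elif prog in IMMUNE_PROGRAMS:
            immune[i] *= effect
    return cancer, immune


def _nb_counts(rng: np.random.Generator, means: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(means).astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, means * dispersion)
    return rng.poisson(lam).astype(float)


# -- generators -----------------------------------------------------------

def generate_bulk_cohort(n_samples: int = 200, n_genes: int = 500,
                         immune_effect: float = 8.0,
                         noise_dispersion: float = 0.3,
                         seed: int = 0,
                         mean_library_size: int = 50_000
                         ) -> tuple[ExpressionMatrix, SyntheticTruth, GeneAnnotation]:
    """Bulk cohort of cancer/immune mixtures with per-sample immune fraction.

    Each sample s draws f_s ~ Uniform(0,1); gene means are the f-weighted
    mixture of the cancer and immune profiles, so SLC2A3 and the immune
    signatures rise with f while SLC2A1, EPCAM and hypoxia genes fall.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    genes, annotation = _gene_table(n_genes)
    base = _base_means(rng, n_genes)
    cancer, immune = _immune_cancer_profiles(base, genes, annotation, immune_effect)

    f = rng.uniform(0.0, 1.0, size=n_samples)
    means = (1.0 - f)[None, :] * cancer[:, None] + f[None, :] * immune[:, None]
    scale = mean_library_size / means.sum(axis=0).mean()
    means *= scale
    counts = _nb_counts(rng, means, noise_dispersion)

    obs = [f"sample{i:04d}" for i in range(n_samples)]
    matrix = ExpressionMatrix(counts, genes, obs, "counts")
    truth = SyntheticTruth(
        seed=seed,
        immune_fraction={o: float(v) for o, v in zip(obs, f)},
        effect_sizes={"immune_effect": float(immune_effect)},
        library_sizes={o: int(round(v)) for o, v in zip(obs, means.sum(axis=0))},
    )
    return matrix, truth, annotation


def _type_profiles(base: np.ndarray, genes: list[str], annotation: GeneAnnotation,
                   glut_effect: float, marker_effect: float) -> dict[str, np.ndarray]:
    """Canonical markers carry the full marker fold change; accompanying
    program genes (signatures, cytolytic effectors) ride at its square root,
    so the published markers dominate fold-change rankings the way they do in
    real data.  Both factors are 1 when marker_effect is 1."""
    marker_of = annotation.table["is_marker_of"]
    canonical = {g for mks in TYPE_MARKERS.values() for g in mks}
    program_effect = float(np.sqrt(marker_effect))
    profiles = {t: base.copy() for t in CELL_TYPES}
    for i, g in enumerate(genes):
        prog = marker_of.loc[g]
        if g == "SLC2A1":
            profiles["cancer"][i] *= glut_effect
        elif g == "SLC2A3":
            for t in ("Tcell", "Bcell", "myeloid"):
                profiles[t][i] *= glut_effect
        elif prog == "cancer" and g == "EPCAM":
            profiles["cancer"][i] *= marker_effect
        elif prog in ("Tcell", "Bcell", "myeloid"):
            factor = marker_effect if g in canonical else program_effect
            profiles[prog][i] *= factor
        elif prog == "immune" and g in ("GZMB", "PRF1", "GZMA"):
            # cytolytic effectors ride the T compartment
            profiles["Tcell"][i] *= program_effect
    return profiles


def generate_sc_counts(n_cells: int = 1000,
                       type_proportions: dict[str, float] | None = None,
                       glut_effect: float = 6.0, marker_effect: float = 6.0,
                       chr7_gain: float | None = None, seed: int = 0,
                       n_genes: int = 800, noise_dispersion: float = 0.3,
                       mean_library_size: int = 5_000
                       ) -> tuple[ExpressionMatrix, SyntheticTruth, GeneAnnotation]:
    """Single-cell counts with four discrete cell types.

    Cancer cells over-express SLC2A1 (by ``glut_effect``) and EPCAM; T, B and
    myeloid cells over-express SLC2A3 and their published markers (CD3D/CD8A/
    CD4, CD79A/IGHM, CD68/LYZ) plus their immune signature genes.  With
    ``chr7_gain``, all chromosome-7 genes are multiplied by the gain in
    cancer cells only (a dosage-gain CNA, GBM-style).
    """
    if n_cells < 40:
        raise ValueError("n_cells must be >= 40")
    if type_proportions is None:
        type_proportions = {"cancer": 0.4, "Tcell": 0.3, "Bcell": 0.1, "myeloid": 0.2}
    props = np.array([type_proportions.get(t, 0.0) for t in CELL_TYPES], dtype=float)
    if np.any(props < 0):
        raise ValueError("cell-type proportions must be non-negative")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"cell-type proportions must sum to 1, got {props.sum()}")

    rng = np.random.default_rng(seed)
    genes, annotation = _gene_table(n_genes)
    base = _base_means(rng, n_genes)
    profiles = _type_profiles(base, genes, annotation, glut_effect, marker_effect)

    labels = rng.choice(len(CELL_TYPES), size=n_cells, p=props)
    chr7_idx = [i for i, g in enumerate(genes)
                if annotation.table.loc[g, "chromosome"] == "7"]

    mean_mat = np.stack([profiles[t] for t in CELL_TYPES], axis=1)  # genes x types
    scale = mean_library_size / (mean_mat.sum(axis=0) @ props)
    mean_mat *= scale
    means = mean_mat[:, labels]
    amplified = np.zeros(n_cells, dtype=bool)
    if chr7_gain is not None:
        if chr7_gain <= 0:
            raise ValueError("chr7_gain must be positive")
        amplified = labels == CELL_TYPES.index("cancer")
        means[np.ix_(chr7_idx, np.flatnonzero(amplified))] *= chr7_gain
    counts = _nb_counts(rng, means, noise_dispersion)

    obs = [f"cell{i:05d}" for i in range(n_cells)]
    matrix = ExpressionMatrix(counts, genes, obs, "counts")
    truth = SyntheticTruth(
        seed=seed,
        cell_type_labels={o: CELL_TYPES[l] for o, l in zip(obs, labels)},
        amplified_flags={o: bool(a) for o, a in zip(obs, amplified)},
        effect_sizes={"glut_effect": float(glut_effect),
                      "marker_effect": float(marker_effect),
                      "chr7_gain": float(chr7_gain) if chr7_gain is not None else 1.0},
        library_sizes={o: int(round(v)) for o, v in zip(obs, means.sum(axis=0))},
    )
    return matrix, truth, annotation


def generate_spatial_grid(width: int = 20, height: int = 20,
                          tumor_region: tuple[int, int, int, int] | None = None,
                          glut_effect: float = 6.0, seed: int = 0,
                          n_genes: int = 800, noise_dispersion: float = 0.3,
                          mean_library_size: int = 8_000
                          ) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Spatial grid of spots: a tumor rectangle (immune fraction ~0.1,
    EPCAM/SLC2A1-high) inside an immune-rich field (immune fraction ~0.7).

    ``tumor_region`` is (row_start, row_stop, col_start, col_stop), half-open,
    strictly inside the ``height`` x ``width`` grid (default: the central
    half of each axis).  Returns the counts matrix, a spot coordinate table
    (index spot_id; columns row, col) and the truth record with per-spot
    immune fractions.
    """
    if width * height < 16:
        raise ValueError("grid must contain at least 16 spots")
    if tumor_region is None:
        tumor_region = (height // 4, 3 * height // 4, width // 4, 3 * width // 4)
    r0, r1, c0, c1 = tumor_region
    if r1 <= r0 or c1 <= c0:
        raise ValueError("tumor_region has zero area")
    if not (0 <= r0 and r1 <= height and 0 <= c0 and c1 <= width):
        raise ValueError("tumor_region must lie inside the grid")

    rng = np.random.default_rng(seed)
    genes, annotation = _gene_table(n_genes)
    base = _base_means(rng, n_genes)
    cancer, immune = _immune_cancer_profiles(base, genes, annotation, glut_effect)

    rows, cols = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    inside = (rows >= r0) & (rows < r1) & (cols >= c0) & (cols < c1)
    f = np.where(inside, 0.1, 0.7) + rng.uniform(-0.05, 0.05, size=rows.size)
    f = np.clip(f, 0.0, 1.0)

    means = (1.0 - f)[None, :] * cancer[:, None] + f[None, :] * immune[:, None]
    means *= mean_library_size / means.sum(axis=0).mean()
    counts = _nb_counts(rng, means, noise_dispersion)

    obs = [f"spot_{r}_{c}" for r, c in zip(rows, cols)]
    matrix = ExpressionMatrix(counts, genes, obs, "counts")
    coords = pd.DataFrame({"row": rows, "col": cols},
                          index=pd.Index(obs, name="spot_id"))
    truth = SyntheticTruth(
        seed=seed,
        immune_fraction={o: float(v) for o, v in zip(obs, f)},
        effect_sizes={"glut_effect": float(glut_effect)},
        library_sizes={o: int(round(v)) for o, v in zip(obs, means.sum(axis=0))},
    )
    return matrix, coords, truth


def immune_program_genes(annotation: GeneAnnotation) -> list[str]:
    """Genes planted on the immune side (pan-immune + T/B/myeloid programs)."""
    return annotation.genes_of_program(IMMUNE_PROGRAMS)


def tumor_region_mask(coords: pd.DataFrame,
                      tumor_region: tuple[int, int, int, int]) -> np.ndarray:
    r0, r1, c0, c1 = tumor_region
    return ((coords["row"] >= r0) & (coords["row"] < r1)
            & (coords["col"] >= c0) & (coords["col"] < c1)).to_numpy()
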