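"""Readers and writers for the plain-text formats the pipeline touches.

Counts travel as MatrixMarket MTX with one-identifier-per-line sidecar files
(genes file <-> rows, observations file <-> columns, 10x-style) or as a dense
TSV with genes as rows.  Gene sets travel as GMT.  All writers are inverses
of the corresponding readers on valid input.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .matrix import ExpressionMatrix, GeneAnnotation, GeneSetCollection, ScoreTable


def _read_id_file(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _write_id_file(ids: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")


def read_counts(path_matrix, path_genes=None, path_obs=None) -> ExpressionMatrix:
    """Read a counts matrix from MTX + sidecars, or from a dense TSV.

    With ``path_genes``/``path_obs`` given, ``path_matrix`` is MatrixMarket;
    otherwise it is a TSV with gene ids in the first column and observation
    ids in the header.
    """
    path_matrix = Path(path_matrix)
    if path_genes is None and path_obs is None:
        df = pd.read_csv(path_matrix, sep="\t", index_col=0)
        return ExpressionMatrix(df.to_numpy(dtype=float), list(df.index.astype(str)),
                                list(df.columns.astype(str)), "counts")
    mat = mmread(str(path_matrix))
    genes = _read_id_file(path_genes)
    obs = _read_id_file(path_obs)
    if mat.shape[0] != len(genes):
        raise ValueError(
            f"matrix declares {mat.shape[0]} rows but gene file has {len(genes)} ids"
        )
    if mat.shape[1] != len(obs):
        raise ValueError(
            f"matrix declares {mat.shape[1]} columns but observation file has {len(obs)} ids"
        )
    return ExpressionMatrix(sp.csr_matrix(mat), genes, obs, "counts")


def write_counts(matrix: ExpressionMatrix, path_prefix) -> dict[str, Path]:
    """Write a counts matrix as ``<prefix>.mtx`` + ``<prefix>.genes.txt`` +
    ``<prefix>.obs.txt``; returns the paths written."""
    if matrix.layer_tag != "counts":
        raise ValueError(f"write_counts expects layer_tag='counts', got {matrix.layer_tag!r}")
    dense = matrix.dense()
    if not np.allclose(dense, np.round(dense)):
        raise ValueError("counts layer contains non-integer entries")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": prefix.with_suffix(".mtx"),
        "genes": Path(f"{prefix}.genes.txt"),
        "obs": Path(f"{prefix}.obs.txt"),
    }
    mmwrite(str(paths["matrix"]), sp.coo_matrix(dense.astype(int)))
    _write_id_file(matrix.gene_ids, paths["genes"])
    _write_id_file(matrix.obs_ids, paths["obs"])
    return paths


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, genes... per tab-separated line)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            coll.add(name, genes, desc)
    return coll


def write_gmt(collection: GeneSetCollection, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name in collection.names():
            genes = "\t".join(collection[name])
            fh.write(f"{name}\t{collection.descriptions[name]}\t{genes}\n")
    return path


# -- auxiliary tables -----------------------------------------------------

def write_score_table(table: ScoreTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = table.to_frame()
    df.index.name = "obs_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_score_table(path) -> ScoreTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ScoreTable(list(df.index.astype(str)),
                      {c: df[c].to_numpy(dtype=float) for c in df.columns})


def write_coords(coords: pd.DataFrame, path) -> Path:
    """Write spot coordinates as TSV with columns spot_id, row, col."""
    path = Path(path)
    out = coords.reset_index()
    out.columns = ["spot_id", "row", "col"]
    out.to_csv(path, sep="\t", index=False)
    return path


def read_coords(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"spot_id": str})
    return df.set_index("spot_id")[["row", "col"]].astype(int)


def write_annotation(annotation: GeneAnnotation, path) -> Path:
    path = Path(path)
    out = annotation.table.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    return path


def read_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", index_col="gene_id",
                     dtype={"chromosome": str}, keep_default_na=False, na_values=[""])
    return GeneAnnotation(df)


def write_truth(truth, path) -> Path:
    """Serialize a SyntheticTruth record as JSON."""
    path = Path(path)

    def _clean(m):
        if m is None:
            return None
        return {str(k): (bool(v) if isinstance(v, (bool, np.bool_)) else
                         float(v) if isinstance(v, (float, np.floating)) else int(v)
                         if isinstance(v, (int, np.integer)) else v)
                for k, v in m.items()}

    payload = {
        "seed": int(truth.seed),
        "immune_fraction": _clean(truth.immune_fraction),
        "cell_type_labels": dict(truth.cell_type_labels) if truth.cell_type_labels else None,
        "amplified_flags": _clean(truth.amplified_flags),
        "effect_sizes": {k: float(v) for k, v in truth.effect_sizes.items()},
        "library_sizes": _clean(truth.library_sizes),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path
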