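"""Run configuration: the pipeline's tunable parameters and their defaults.

Defaults follow the standard single-cell toolchain conventions this pipeline
mirrors: 2000 highly variable genes, 10 principal components, k=20 SNN
neighbours, top-50 anchor-correlated genes for spatial modules, |logFC|>0.25
and FDR<0.05 marker gates.  The clustering resolution is dataset-dependent
(e.g. 1.0 breast, 0.3 HNSC, 0.2 GBM, 0.5 melanoma-ICI cohorts).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    n_hvg: int = 2000
    n_pcs: int = 10
    cluster_resolution: float = 1.0
    knn_k: int = 20
    topk_corr: int = 50
    de_logfc: float = 0.25
    de_fdr: float = 0.05
    go_p: float = 0.05
    go_fdr: float = 0.2
    module_nbin: int = 24
    module_nctrl: int = 100
    ssgsea_alpha: float = 0.25
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hvg", "n_pcs", "knn_k", "topk_corr", "module_nbin", "module_nctrl"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in ("cluster_resolution", "de_logfc", "ssgsea_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("de_fdr", "go_p", "go_fdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be strictly positive")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(RunConfig)}
_INT_FIELDS = {"n_hvg", "n_pcs", "knn_k", "topk_corr", "module_nbin", "module_nctrl", "seed"}


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from a flat ``key = value`` text file and/or overrides.

    Unknown keys and out-of-range values are rejected; unspecified keys take
    the documented defaults.
    """
    values: dict[str, object] = {}
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected 'key = value', got {line!r}")
            key, raw = (part.strip() for part in line.split("=", 1))
            values[key] = raw
    values.update(overrides)

    kwargs: dict[str, object] = {}
    for key, raw in values.items():
        if key not in _FIELD_TYPES:
            raise ValueError(f"unknown config key: {key!r}")
        if isinstance(raw, str):
            raw = int(raw) if key in _INT_FIELDS else float(raw)
        elif key in _INT_FIELDS:
            raw = int(raw)
        else:
            raw = float(raw)
        kwargs[key] = raw
    return RunConfig(**kwargs)
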