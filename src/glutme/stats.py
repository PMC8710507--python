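"""Statistical kernel shared by every stage: rank tests, correlation,
Benjamini-Hochberg FDR, and hypergeometric over-representation.

The Mann-Whitney U test is implemented here rather than delegated because the
pipeline's contract requires an exact-enumeration branch for small groups
(both sizes <= 8, ties allowed) and a tie-corrected normal approximation
otherwise; scipy's exact method refuses ties.  Distribution tails, the
Kruskal-Wallis H test and Pearson's r come from scipy; BH adjustment from
statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALTERNATIVES = ("two-sided", "greater", "less")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value outside [0,1]: {self.p_value}")


@dataclass
class EnrichmentRow:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    fdr: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.query_size):
            raise ValueError("overlap exceeds set or query size")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x: #{x_i > y_j} + 0.5 #{x_i = y_j} via rank sums."""
    n, m = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[:n].sum() - n * (n + 1) / 2.0)


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test of two independent samples.

    Exact p by full enumeration of all C(n+m, n) group labelings when both
    groups have <= 8 observations (correct under ties); otherwise the
    tie-corrected normal approximation.  ``alternative='greater'`` tests
    whether x tends to exceed y.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(x, y)

    if n <= 8 and m <= 8:
        pooled = np.concatenate([x, y])
        us = np.array([
            _u_statistic(pooled[list(idx)],
                         pooled[[i for i in range(n + m) if i not in set(idx)]])
            for idx in combinations(range(n + m), n)
        ])
        eps = 1e-9
        p_ge = float(np.mean(us >= u - eps))
        p_le = float(np.mean(us <= u + eps))
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return TestResult(u, p, (n, m), "mann-whitney-exact")

    mean = n * m / 2.0
    N = n + m
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n * m / 12.0 * (N + 1 - tie_term / (N * (N - 1)))
    if var <= 0:  # all observations identical
        p = 1.0
        return TestResult(u, p, (n, m), "mann-whitney-normal")
    z = (u - mean) / np.sqrt(var)
    if alternative == "greater":
        p = float(sps.norm.sf(z))
    elif alternative == "less":
        p = float(sps.norm.cdf(z))
    else:
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(u, p, (n, m), "mann-whitney-normal")


def mann_whitney_matrix(a: np.ndarray, b: np.ndarray,
                        alternative: str = "two-sided") -> tuple[np.ndarray, np.ndarray]:
    """Row-wise tie-corrected normal-approximation Mann-Whitney U.

    ``a`` and ``b`` are (n_genes, n_cells) blocks of the two groups; returns
    per-row (U, p).  Used by the marker-detection stage where thousands of
    genes are tested at once.
    """
    n, m = a.shape[1], b.shape[1]
    N = n + m
    pooled = np.concatenate([a, b], axis=1)
    ranks = sps.rankdata(pooled, axis=1)
    u = ranks[:, :n].sum(axis=1) - n * (n + 1) / 2.0
    # tie correction per row
    srt = np.sort(pooled, axis=1)
    tie_term = np.zeros(pooled.shape[0])
    for i in range(pooled.shape[0]):
        _, counts = np.unique(srt[i], return_counts=True)
        tie_term[i] = np.sum(counts**3 - counts)
    var = n * m / 12.0 * (N + 1 - tie_term / (N * (N - 1)))
    mean = n * m / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - mean) / np.sqrt(var)
    if alternative == "greater":
        p = sps.norm.sf(z)
    elif alternative == "less":
        p = sps.norm.cdf(z)
    else:
        p = np.minimum(1.0, 2.0 * sps.norm.sf(np.abs(z)))
    p = np.where(var <= 0, 1.0, p)
    return u, p


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test across >=2 groups."""
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError("at least two groups required")
    if any(len(g) == 0 for g in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    sizes = tuple(len(g) for g in arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, sizes, "kruskal-wallis")
    h, p = sps.kruskal(*arrays)
    return TestResult(float(h), float(p), sizes, "kruskal-wallis")


def pearson_corr_test(x, y) -> TestResult:
    """Pearson's r with the two-sided t-transform p on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue), (len(x),), "pearson")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrichment(query: Sequence[str], collection, universe: Sequence[str],
                         p_max: float = 0.05, fdr_max: float = 0.2,
                         keep_all: bool = False) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    Each set is intersected with the universe before testing; BH adjustment is
    applied across all tested sets; rows passing ``p < p_max`` and
    ``fdr < fdr_max`` are returned sorted by p (all rows if ``keep_all``).
    """
    query = list(query)
    if len(set(query)) != len(query):
        raise ValueError("duplicate genes in query")
    uni = set(universe)
    missing = [g for g in query if g not in uni]
    if missing:
        raise ValueError(f"query gene outside universe: {missing[0]!r}")
    qset = set(query)
    M, N = len(uni), len(query)
    names, ps, overlaps, sizes = [], [], [], []
    for name in collection.names():
        members = set(collection[name]) & uni
        if not members:
            continue
        k = len(members & qset)
        p = float(sps.hypergeom.sf(k - 1, M, len(members), N))
        names.append(name)
        ps.append(p)
        overlaps.append(k)
        sizes.append(len(members))
    fdrs = bh_fdr(ps) if ps else np.array([])
    rows = [
        EnrichmentRow(name, k, sz, N, M, p, float(f))
        for name, k, sz, p, f in zip(names, overlaps, sizes, ps, fdrs)
    ]
    if not keep_all:
        rows = [r for r in rows if r.p_value < p_max and r.fdr < fdr_max]
    return sorted(rows, key=lambda r: r.p_value)


def significance_stars(p: float) -> str:
    """Figure-legend style stars: *p<0.05, **p<0.01, ***p<0.001, ****p<0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"
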