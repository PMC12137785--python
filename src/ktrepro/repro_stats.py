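"""Reproducibility statistics on CV tables.

A *CV table* holds the coefficient of variation (percent) of the flip angle
for ``V`` subjects across ``S`` scan groups under one shim method. Three
cluster statistics summarize the table in CV space:

* ``ICV`` (inertia): mean squared deviation of the cells from the per-scan
  centroid, ``(1 / (V S)) * sum_v sum_s (CV_{v,s} - xbar_s)^2``. Measures
  the dispersion of the cluster; reported on the squared-percent scale with
  a square-rooted convenience companion.
* ``|xbar|``: Euclidean norm of the centroid ``xbar = (xbar_1 .. xbar_S)``.
  Measures the overall magnitude of the CVs.
* ``d_perp``: Euclidean distance from the centroid to the identity line
  ``{(t, .., t)}`` in S-space, ``sqrt(sum_s (m - xbar_s)^2)`` with ``m`` the
  mean of the centroid components. Measures inter-session consistency:
  zero iff all per-scan centroids agree.

Small values of all three indicate a method that is reproducible across
scan sessions while keeping CVs low. Pairwise method comparisons use the
Wilcoxon signed-rank test (exact enumeration for small n) with Bonferroni
correction over the comparison family.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata


@dataclass
class CVTable:
    """Subjects x scan-groups matrix of CV values (%) for one shim method."""

    method: str
    values: np.ndarray  # (V, S)
    subjects: list[str] | None = None
    sessions: list[int] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("CV table must be a non-empty 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CV table has missing or non-finite cells")
        if np.any(self.values < 0):
            raise ValueError("CV values must be non-negative")
        if self.subjects is None:
            self.subjects = [f"S{v + 1}" for v in range(self.n_subjects)]
        if self.sessions is None:
            self.sessions = list(range(1, self.n_sessions + 1))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.values.shape[1]

    def centroid(self) -> np.ndarray:
        """Per-scan-group mean over subjects, xbar_s."""
        return self.values.mean(axis=0)


def inertia(table: CVTable) -> float:
    """Cluster dispersion ICV (squared-percent scale)."""
    x = table.values
    if x.size == 0:
        raise ValueError("empty CV table")
    return float(np.mean((x - table.centroid()) ** 2))


def centroid_norm(table: CVTable) -> float:
    """Euclidean norm of the cluster centroid, |xbar| (%)."""
    return float(np.linalg.norm(table.centroid()))


def perp_distance(table: CVTable) -> float:
    """Distance from the centroid to the identity line, d_perp (%)."""
    xbar = table.centroid()
    m = xbar.mean()
    return float(np.sqrt(np.sum((m - xbar) ** 2)))


@dataclass(frozen=True)
class ClusterSummary:
    """All cluster statistics of one method's CV table."""

    method: str
    centroid: tuple[float, ...]
    icv: float
    root_icv: float
    centroid_norm: float
    perp_distance: float
    median_point: tuple[float, ...]  # componentwise median, for plotting parity


def cluster_summary(table: CVTable) -> ClusterSummary:
    icv = inertia(table)
    return ClusterSummary(
        method=table.method,
        centroid=tuple(table.centroid()),
        icv=icv,
        root_icv=float(np.sqrt(icv)),
        centroid_norm=centroid_norm(table),
        perp_distance=perp_distance(table),
        median_point=tuple(np.median(table.values, axis=0)),
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

EXACT_N_MAX = 12


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of ranks of positive differences) and the tie-averaged ranks."""
    ranks = rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def paired_rank_test(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (Wilcoxon's original rule). For n <= 12
    remaining pairs the exact null distribution is computed by enumerating
    all 2^n sign assignments of the (tie-averaged) ranks; otherwise a normal
    approximation with tie correction is used. If every difference is zero
    the test is degenerate and p = 1 is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; returning p = 1")
        return 1.0
    w_obs, ranks = _signed_rank_statistic(d)

    if n <= EXACT_N_MAX:
        # All 2^n sign assignments: bit j of each integer decides whether
        # rank j contributes to W+.
        masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1  # (2^n, n)
        sums = masks @ ranks
        p_le = np.mean(sums <= w_obs + 1e-12)
        p_ge = np.mean(sums >= w_obs - 1e-12)
        return float(min(1.0, 2.0 * min(p_le, p_ge)))

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # Tie correction on the ranks of |d|.
    _, counts = np.unique(ranks, return_counts=True)
    var -= np.sum(counts**3 - counts) / 48.0
    if var <= 0:
        warnings.warn("degenerate rank variance; returning p = 1")
        return 1.0
    z = (w_obs - mean) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def bonferroni(pvals, alpha: float = 0.05, m: int | None = None):
    """Bonferroni significance flags: ``True`` iff p < alpha / m.

    ``m`` defaults to the number of p-values (the comparison family size).
    Returns ``(flags, threshold)``.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("no p-values supplied")
    m = int(m) if m is not None else pvals.size
    if m < 1:
        raise ValueError("family size must be >= 1")
    threshold = alpha / m
    return pvals < threshold, threshold


def pairwise_test_matrix(
    tables: dict[str, CVTable], alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise method comparisons within one study grouping.

    Each comparison pairs the flattened (subject, scan-group) CV cells of
    two methods; the Bonferroni family is the full set of pairs and its
    size ``m`` is recorded in the output.
    """
    methods = list(tables)
    pairs = list(itertools.combinations(methods, 2))
    if not pairs:
        raise ValueError("need at least two methods to compare")
    pvals = []
    for a, b in pairs:
        ta, tb = tables[a], tables[b]
        if ta.values.shape != tb.values.shape:
            raise ValueError(f"tables {a} and {b} have different shapes")
        pvals.append(paired_rank_test(ta.values.ravel(), tb.values.ravel()))
    flags, threshold = bonferroni(pvals, alpha=alpha)
    return pd.DataFrame(
        {
            "method_a": [a for a, _ in pairs],
            "method_b": [b for _, b in pairs],
            "p_value": pvals,
            "m": len(pairs),
            "threshold": threshold,
            "significant": ["S" if f else "NS" for f in flags],
        }
    )


class CVClusterAnalysis:
    """Results-style wrapper: cluster statistics for a family of CV tables."""

    def __init__(self, tables: dict[str, CVTable]):
        if not tables:
            raise ValueError("no CV tables supplied")
        self.tables = tables

    def summaries(self) -> pd.DataFrame:
        rows = []
        for name, t in self.tables.items():
            s = cluster_summary(t)
            rows.append(
                {
                    "method": name,
                    "icv": s.icv,
                    "root_icv": s.root_icv,
                    "centroid_norm": s.centroid_norm,
                    "perp_distance": s.perp_distance,
                }
            )
        return pd.DataFrame(rows)

    def tests(self, alpha: float = 0.05) -> pd.DataFrame:
        return pairwise_test_matrix(self.tables, alpha=alpha)

    def summary(self) -> str:
        df = self.summaries()
        lines = ["CV-cluster reproducibility summary", "=" * 48]
        for _, r in df.iterrows():
            lines.append(
                f"{r['method']:>10s}  ICV={r['icv']:8.3f}  |xbar|={r['centroid_norm']:7.3f}"
                f"  d_perp={r['perp_distance']:7.3f}"
            )
        return "\n".join(lines)
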