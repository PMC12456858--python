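"""Group statistics on region-wise signal: log10 fold changes,
Kruskal-Wallis with Dunn's post hoc test and Benjamini-Hochberg FDR,
hierarchical laminar clustering and subtraction heatmaps.

Region signal sums span orders of magnitude and contain exact zeros in
sparsely innervated regions, hence the nonparametric tests and the
pseudocount used for log scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

__all__ = [
    "log10_fold_change",
    "kruskal_dunn_fdr",
    "GroupComparison",
    "compare_groups",
    "cluster_rows",
    "linkage_to_newick",
    "subtraction_heatmap",
]

DEFAULT_EPSILON = 1.0  # intensity units on the summed-intensity scale


def log10_fold_change(values_a: Sequence[float], values_b: Sequence[float],
                      epsilon: float = DEFAULT_EPSILON) -> float:
    """log10 of the ratio of group means, with pseudocount epsilon.

    Computes log10((mean(A) + eps) / (mean(B) + eps)).  The
    pseudocount keeps regions with zero signal finite; with eps
    negligible relative to the means, a tenfold difference gives 1.0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("fold change of an empty group is undefined")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("signal values must be >= 0")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return float(np.log10((a.mean() + epsilon) / (b.mean() + epsilon)))


@dataclass
class GroupComparison:
    """Result of one Kruskal-Wallis + Dunn family for a single region."""

    h_statistic: float
    p_value: float
    dunn_z: dict[tuple[int, int], float]
    dunn_p: dict[tuple[int, int], float]


def kruskal_dunn_fdr(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H plus Dunn pairwise z tests.

    Dunn's z for groups i, j uses the pooled mid-ranks:
    z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    with tie correction T = sum(t^3 - t) / (12 (N - 1)); p values are
    two-sided normal.  When every pooled value is identical the rank
    variance is zero and the defined result is H = 0, all p = 1.

    The Benjamini-Hochberg adjustment is applied by the caller across
    the full declared family (all regions x pairs); see
    :func:`compare_groups`.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs >= 1 value")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    if np.all(pooled == pooled[0]):
        pairs = list(combinations(range(len(arrays)), 2))
        return GroupComparison(0.0, 1.0, {p: 0.0 for p in pairs}, {p: 1.0 for p in pairs})

    h, p = sps.kruskal(*arrays)
    ranks = sps.rankdata(pooled)
    sizes = [a.size for a in arrays]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [ranks[offsets[i]:offsets[i + 1]].mean() for i in range(len(arrays))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    pooled_var = n_total * (n_total + 1) / 12.0 - tie_term
    dunn_z, dunn_p = {}, {}
    for i, j in combinations(range(len(arrays)), 2):
        se = np.sqrt(pooled_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        dunn_z[(i, j)] = float(z)
        dunn_p[(i, j)] = float(2.0 * sps.norm.sf(abs(z)))
    return GroupComparison(float(h), float(p), dunn_z, dunn_p)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(values: Mapping[str, Mapping[str, Sequence[float]]],
                   epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Region-wise group comparison table with family-wide FDR.

    ``values`` maps region name -> {group name -> per-sample values}.
    Output rows are one per (region, group pair) carrying log10 group
    means, log10FC (first group of the pair over the second), the
    region's Kruskal-Wallis H and p, Dunn z and raw p for the pair,
    and the Benjamini-Hochberg adjusted p computed across ALL regions
    x pairs (the broadest, most conservative family).
    """
    rows = []
    for region, by_group in values.items():
        names = list(by_group)
        comp = kruskal_dunn_fdr([by_group[g] for g in names])
        for (i, j), z in comp.dunn_z.items():
            a, b = names[i], names[j]
            rows.append({
                "region": region, "group_a": a, "group_b": b,
                "log10_mean_a": float(np.log10(np.mean(by_group[a]) + epsilon)),
                "log10_mean_b": float(np.log10(np.mean(by_group[b]) + epsilon)),
                "log10_fc": log10_fold_change(by_group[a], by_group[b], epsilon),
                "kw_h": comp.h_statistic, "kw_p": comp.p_value,
                "dunn_z": z, "dunn_p": comp.dunn_p[(i, j)],
            })
    df = pd.DataFrame(rows)
    if len(df):
        df["dunn_p_adj"] = fdr_adjust(df["dunn_p"].to_numpy())
    return df


def cluster_rows(matrix: np.ndarray | pd.DataFrame
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative row clustering: Euclidean distance, complete linkage.

    Returns (leaf order, linkage matrix).  With fewer than 2 rows the
    identity order and an empty linkage are returned.  Ties in merge
    distance resolve toward the lower original row index (scipy's
    deterministic ordering), so identical inputs always give identical
    dendrograms.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError("cluster_rows expects a 2-D matrix")
    if not np.isfinite(arr).all():
        raise ValueError("matrix must be finite")
    if arr.shape[0] < 2:
        return np.arange(arr.shape[0]), np.empty((0, 4))
    link = hierarchy.linkage(arr, method="complete", metric="euclidean")
    order = hierarchy.leaves_list(link)
    return order, link


def linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick tree string."""
    n = len(labels)
    if link.shape[0] == 0:
        return "(" + ",".join(labels) + ");" if n > 1 else f"{labels[0]};" if n else ";"

    def node(idx: int) -> str:
        if idx < n:
            return str(labels[idx])
        a, b, dist, _ = link[idx - n]
        return f"({node(int(a))},{node(int(b))}):{dist:.6g}"

    return node(2 * n - 2) + ";"


def subtraction_heatmap(means_a: pd.DataFrame | np.ndarray,
                        means_b: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Elementwise A - B of two aligned region-mean matrices."""
    if isinstance(means_a, pd.DataFrame) and isinstance(means_b, pd.DataFrame):
        if not means_a.index.equals(means_b.index) or not means_a.columns.equals(means_b.columns):
            raise ValueError("region mean matrices are not aligned (index/columns differ)")
        return means_a - means_b
    a, b = np.asarray(means_a, dtype=float), np.asarray(means_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"region mean matrices are not aligned: {a.shape} vs {b.shape}")
    return a - b
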