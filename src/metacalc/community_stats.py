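"""Two-group community statistics.

Covers the three comparisons made on the genus abundance matrix: a
two-tailed two-sample t-test per genus on log2-transformed fractions
(Benjamini-Hochberg adjusted across genera), agglomerative hierarchical
clustering of samples under Pearson correlation distance, and Bray-Curtis
dissimilarity on integer count matrices obtained by scaling percent values
by 10^6 with truncation.

Zero fractions are treated as missing for the log2 tests — no pseudo-count
is fabricated — and each genus needs at least two present values per group
to be tested; untested genera are reported with NaN statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .tables_io import ValidationError

__all__ = [
    "ClusterResult",
    "two_group_t_test",
    "pearson_distance",
    "hierarchical_cluster",
    "bray_curtis",
    "scale_percent_to_counts",
]


def two_group_t_test(
    fractions: pd.DataFrame,
    labels: Mapping[str, str],
    group_pair: tuple[str, str] = ("G1", "G2"),
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-genus two-tailed t-test on log2 fractions (group1 - group2).

    ``fractions`` is samples x genera.  Student's pooled-variance t is the
    default; pass ``equal_var=False`` for Welch.  Adjusted p-values are
    Benjamini-Hochberg across the tested genera; ``significant`` marks
    adjusted p <= alpha.  The volcano columns (log2_ratio, -log10 p) come
    for free from the output.
    """
    g1, g2 = group_pair
    samples1 = [s for s in fractions.index if labels.get(s) == g1]
    samples2 = [s for s in fractions.index if labels.get(s) == g2]
    if len(samples1) < 2 or len(samples2) < 2:
        raise ValidationError(
            f"need >= 2 samples per group, got {len(samples1)} vs {len(samples2)}"
        )

    log2f = np.log2(fractions.where(fractions > 0))
    rows = []
    for genus in fractions.columns:
        x = log2f.loc[samples1, genus].dropna().to_numpy()
        y = log2f.loc[samples2, genus].dropna().to_numpy()
        tested = len(x) >= 2 and len(y) >= 2
        if tested:
            ratio = float(x.mean() - y.mean())
            if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
                # degenerate: no within-group spread; equal means are a
                # perfect null fit, unequal means an exact separation
                t_stat = 0.0 if ratio == 0 else np.inf * np.sign(ratio)
                p = 1.0 if ratio == 0 else 0.0
            else:
                t_stat, p = stats.ttest_ind(x, y, equal_var=equal_var)
        else:
            t_stat = p = ratio = np.nan
        rows.append(
            {
                "genus": genus,
                "n_group1": len(x),
                "n_group2": len(y),
                "tested": tested,
                "log2_ratio": ratio,
                "t_statistic": float(t_stat) if tested else np.nan,
                "p_value": float(p) if tested else np.nan,
            }
        )
    result = pd.DataFrame(rows).set_index("genus")

    result["adjusted_p"] = np.nan
    tested_mask = result["tested"].to_numpy()
    if tested_mask.any():
        _, adjusted, _, _ = multipletests(
            result.loc[tested_mask, "p_value"], method="fdr_bh"
        )
        result.loc[tested_mask, "adjusted_p"] = adjusted
    result["significant"] = result["adjusted_p"] <= alpha
    result["neg_log10_p"] = -np.log10(result["p_value"])
    return result.reset_index()


def pearson_distance(
    matrix: pd.DataFrame,
    min_shared: int = 3,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Pairwise-complete Pearson correlation distance between sample columns.

    d(x, y) = 1 - r(x, y) over the entries present in both samples.  Pairs
    sharing fewer than ``min_shared`` entries (or with zero variance) are
    flagged and imputed with the maximum observed distance.
    """
    corr = matrix.corr(method="pearson", min_periods=min_shared)
    dist = 1.0 - corr
    np.fill_diagonal(dist.values, 0.0)
    flagged = [
        (a, b)
        for i, a in enumerate(dist.index)
        for b in dist.columns[i + 1:]
        if np.isnan(dist.loc[a, b])
    ]
    if flagged:
        observed_max = np.nanmax(dist.to_numpy())
        dist = dist.fillna(observed_max if np.isfinite(observed_max) else 2.0)
        np.fill_diagonal(dist.values, 0.0)
    return dist, flagged


@dataclass
class ClusterResult:
    samples: list[str]
    linkage_matrix: np.ndarray  # scipy hierarchy format
    labels: dict[str, int] | None  # flat k-group labels, 1-based
    flagged_pairs: list[tuple[str, str]]

    def linkage_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage_matrix,
            columns=["left", "right", "height", "n_members"],
        )


def hierarchical_cluster(
    matrix: pd.DataFrame,
    linkage: str = "average",
    k: int | None = None,
    min_shared: int = 3,
) -> ClusterResult:
    """Agglomerative clustering of sample columns under Pearson distance.

    ``matrix`` is features x samples, already presence-filtered and
    normalized.  When ``k`` is given the tree is cut into k flat groups.
    Ties in merge heights are resolved deterministically by scipy; sample
    input order does not change the tree beyond label permutation.
    """
    dist, flagged = pearson_distance(matrix, min_shared=min_shared)
    # order-independent canonical ordering of the distance matrix
    order = sorted(dist.index)
    dist = dist.loc[order, order]
    condensed = squareform(dist.to_numpy(), checks=False)
    linkage_matrix = hierarchy.linkage(condensed, method=linkage)
    labels = None
    if k is not None:
        flat = hierarchy.fcluster(linkage_matrix, t=k, criterion="maxclust")
        labels = dict(zip(order, (int(v) for v in flat)))
    return ClusterResult(
        samples=order,
        linkage_matrix=linkage_matrix,
        labels=labels,
        flagged_pairs=flagged,
    )


def scale_percent_to_counts(percent: pd.DataFrame) -> pd.DataFrame:
    """Percent values x 10^6 with decimals truncated toward zero."""
    if (percent < 0).any().any():
        raise ValidationError("percent values must be non-negative")
    return np.trunc(percent * 1_000_000).astype(np.int64)


def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity between sample rows.

    BC(i, j) = 1 - 2 * sum_g min(x_ig, x_jg) / (sum_g x_ig + sum_g x_jg).
    All-zero samples have undefined dissimilarity and yield NaN entries.
    """
    if (counts < 0).any().any():
        raise ValidationError("counts must be non-negative")
    values = counts.to_numpy(dtype=float)
    row_sums = values.sum(axis=1)
    result = pd.DataFrame(
        np.nan, index=counts.index, columns=counts.index, dtype=float
    )
    nonzero = row_sums > 0
    if nonzero.any():
        sub = values[nonzero]
        condensed = pdist(sub, metric="braycurtis")
        square = squareform(condensed)
        idx = counts.index[nonzero]
        result.loc[idx, idx] = square
    for sample, ok in zip(counts.index, nonzero):
        result.loc[sample, sample] = 0.0 if ok else np.nan
    return result
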