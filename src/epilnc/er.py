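"""Epigenetically regulated (ER) lncRNA detection.

An ER lncRNA is differentially methylated between the two subtypes
(|Δβ| > 0.2 at BH-FDR < 0.05 by Wilcoxon rank-sum) *and* shows a
significant negative Pearson correlation between promoter methylation
and expression across the cohort. The Δβ sign convention is
``mean(cluster 1) − mean(cluster 2)`` with cluster 1 the immune-hot
cluster, so a hypomethylated-in-hot feature has Δβ < 0.

This module also hosts the shared nonparametric primitives (rank-sum
test, BH step-up, Pearson) used by the immune-scoring and evasion
stages.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "wilcoxon_rank_sum",
    "bh_fdr",
    "pearson",
    "differential_methylation",
    "classify_er",
]


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both samples are small (min n <= 8) and
    untied; otherwise the normal approximation with tie and continuity
    correction. Two identical constant groups give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-distribution p (n-2 df).

    Pairs with a missing value in either vector are dropped; fewer than
    3 complete pairs or a constant vector raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def differential_methylation(
    prom_meth: pd.DataFrame,
    labels: pd.Series,
    min_per_group: int = 3,
) -> pd.DataFrame:
    """Per-feature subtype methylation difference.

    *labels* must contain exactly two clusters; cluster 1 is the first
    in sorted order (the pipeline assigns 1 to the immune-hot cluster).
    Returns a DataFrame with ``delta_beta`` (mean cluster1 − mean
    cluster2), ``p_dm`` and ``fdr_dm``. Features with fewer than
    *min_per_group* non-missing values in either group are excluded with
    a warning.
    """
    labels = labels.loc[labels.index.intersection(prom_meth.columns)]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two clusters, got {groups}")
    s1 = labels.index[labels == groups[0]]
    s2 = labels.index[labels == groups[1]]
    a = prom_meth[s1].to_numpy(dtype=float)
    b = prom_meth[s2].to_numpy(dtype=float)

    n1 = np.sum(np.isfinite(a), axis=1)
    n2 = np.sum(np.isfinite(b), axis=1)
    testable = (n1 >= min_per_group) & (n2 >= min_per_group)
    if not testable.all():
        warnings.warn(
            f"{int((~testable).sum())} features with < {min_per_group} values per group excluded"
        )

    rows = []
    for i in np.flatnonzero(testable):
        xa = a[i][np.isfinite(a[i])]
        xb = b[i][np.isfinite(b[i])]
        delta = float(xa.mean() - xb.mean())
        _, p = wilcoxon_rank_sum(xa, xb)
        rows.append((prom_meth.index[i], delta, p))
    out = pd.DataFrame(rows, columns=["gene_id", "delta_beta", "p_dm"]).set_index("gene_id")
    out["fdr_dm"] = bh_fdr(out["p_dm"].to_numpy())
    return out


def classify_er(
    dm_table: pd.DataFrame,
    prom_meth: pd.DataFrame,
    expr: pd.DataFrame,
    delta_thresh: float = 0.2,
    alpha: float = 0.05,
    require_corr_p: bool = True,
) -> pd.DataFrame:
    """Combine differential methylation with methylation-expression coupling.

    ``is_er`` requires |Δβ| > *delta_thresh*, DM FDR < *alpha*, Pearson
    r < 0 and (when *require_corr_p*) correlation p < *alpha*. The
    correlation is cohort-wide over all samples shared by the two
    matrices. ``direction`` is "hypo_up" for features hypomethylated in
    the hot cluster (Δβ < 0), else "hyper_down".
    """
    shared = prom_meth.columns.intersection(expr.columns)
    records = []
    for gene_id, row in dm_table.iterrows():
        if gene_id not in expr.index:
            warnings.warn(f"{gene_id} missing from expression matrix; excluded")
            continue
        m = prom_meth.loc[gene_id, shared].to_numpy(dtype=float)
        e = expr.loc[gene_id, shared].to_numpy(dtype=float)
        try:
            r, p_corr = pearson(m, e)
        except ValueError:
            warnings.warn(f"{gene_id}: correlation undefined; excluded")
            continue
        is_er = (
            abs(row["delta_beta"]) > delta_thresh
            and row["fdr_dm"] < alpha
            and r < 0
            and (p_corr < alpha or not require_corr_p)
        )
        records.append(
            {
                "gene_id": gene_id,
                "delta_beta": row["delta_beta"],
                "p_dm": row["p_dm"],
                "fdr_dm": row["fdr_dm"],
                "pearson_r": r,
                "p_corr": p_corr,
                "is_er": bool(is_er),
                "direction": "hypo_up" if row["delta_beta"] < 0 else "hyper_down",
            }
        )
    return pd.DataFrame(records).set_index("gene_id")
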