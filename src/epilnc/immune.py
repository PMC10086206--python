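"""Immune scoring and immune-related lncRNA prioritization.

Implements the formula-defined scores of the tumor immune
microenvironment characterization:

* ssGSEA per-sample signature activity (rank-weighted ECDF difference);
* CYT, the geometric mean of GZMA and PRF1 on the linear scale;
* MHC, the mean log2 expression of an MHC class I set;
* an ESTIMATE-like purity surrogate (stromal + immune ssGSEA sum);
* nonparametric differential expression (Wilcoxon + log fold change);
* lncRNA-infiltration correlation filtering with the opposite-direction
  rule (expression and methylation must correlate with a cell type in
  opposite directions, both significant);
* the partial-correlation GSEA linking a lncRNA to immune pathways:
  protein-coding genes are ranked by their purity-adjusted partial
  correlation with the lncRNA and the ranked list is tested against
  each pathway with a permutation null.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .er import bh_fdr, wilcoxon_rank_sum

__all__ = [
    "ssgsea",
    "signature_scores",
    "cyt_score",
    "mhc_score",
    "estimate_like",
    "differential_expression",
    "infiltration_correlation",
    "partial_correlation",
    "gsea_es",
    "lncrna_pathway_association",
    "purity_from_estimate",
]


def _rank_order(values: pd.Series) -> pd.Index:
    """Descending order of genes; ties break by gene id for determinism."""
    df = pd.DataFrame({"v": values})
    df["g"] = df.index
    df = df.sort_values(["v", "g"], ascending=[False, True])
    return df.index


def ssgsea(expr_column: pd.Series, gene_set: set[str], alpha: float = 0.25) -> float:
    """Single-sample GSEA enrichment score for one sample.

    Genes are ranked by expression descending; position i from the top
    carries absolute rank value ``n - i`` (the top gene weighs n). The
    score is the summed difference between the weighted ECDF of in-set
    genes (weights ``rank**alpha``) and the unweighted ECDF of
    out-of-set genes — so it depends on the expression values only
    through their order.
    """
    order = _rank_order(expr_column)
    n = len(order)
    in_set = np.fromiter((g in gene_set for g in order), dtype=bool, count=n)
    n_in = int(in_set.sum())
    if n_in == 0:
        warnings.warn("gene set has no member in the ranking")
        return float("nan")
    if n_in == n:
        raise ValueError("gene set covers the whole ranking")
    ranks = np.arange(n, 0, -1, dtype=float)
    w = np.where(in_set, np.abs(ranks) ** alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_set) / (n - n_in)
    return float(np.sum(p_in - p_out))


def signature_scores(
    expr: pd.DataFrame, sets: dict[str, set[str]], alpha: float = 0.25
) -> pd.DataFrame:
    """ssGSEA score per sample (rows) and signature (columns)."""
    out = pd.DataFrame(index=expr.columns, columns=list(sets), dtype=float)
    for sample in expr.columns:
        col = expr[sample]
        for name, members in sets.items():
            out.loc[sample, name] = ssgsea(col, members, alpha=alpha)
    return out


def cyt_score(expr: pd.DataFrame, pseudocount: float = 0.01) -> pd.Series:
    """Cytolytic activity: geometric mean of GZMA and PRF1 (linear scale).

    log2 values are back-transformed with ``2**x - 1`` before the
    geometric mean; the pseudocount guards zero expression.
    """
    for g in ("GZMA", "PRF1"):
        if g not in expr.index:
            raise KeyError(f"{g} missing from expression matrix")
    gzma = np.power(2.0, expr.loc["GZMA"].astype(float)) - 1.0
    prf1 = np.power(2.0, expr.loc["PRF1"].astype(float)) - 1.0
    score = np.sqrt((gzma + pseudocount) * (prf1 + pseudocount))
    return pd.Series(score, index=expr.columns, name="CYT")


def mhc_score(expr: pd.DataFrame, mhc1_set: set[str]) -> pd.Series:
    """Antigen presentation: mean log2 expression over present MHC-I genes."""
    present = expr.index.intersection(sorted(mhc1_set))
    if len(present) == 0:
        raise ValueError("no MHC-I set member present in the expression matrix")
    return expr.loc[present].mean(axis=0).rename("MHC")


def estimate_like(
    expr: pd.DataFrame, stromal_set: set[str], immune_set: set[str], alpha: float = 0.25
) -> pd.DataFrame:
    """Purity surrogate: stromal and immune ssGSEA components and their sum.

    This reproduces the score's structure (two compartment enrichments
    combined additively), not any published fitted coefficients.
    """
    comp = signature_scores(expr, {"stromal": stromal_set, "immune": immune_set}, alpha=alpha)
    comp["combined"] = comp["stromal"] + comp["immune"]
    return comp


def purity_from_estimate(combined: pd.Series) -> pd.Series:
    """Tumor purity proxy: 1 − min-max-scaled combined ESTIMATE-like score."""
    lo, hi = combined.min(), combined.max()
    if hi == lo:
        return pd.Series(0.5, index=combined.index, name="purity")
    return (1.0 - (combined - lo) / (hi - lo)).rename("purity")


def differential_expression(
    expr: pd.DataFrame,
    labels: pd.Series,
    logfc_thresh: float = 0.75,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group Wilcoxon differential expression on log2 values.

    ``logFC`` is mean(group 1) − mean(group 2) on the log2 scale;
    ``flag`` marks |logFC| > *logfc_thresh* at BH-FDR < *alpha*.
    """
    labels = labels.loc[labels.index.intersection(expr.columns)]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("expected exactly two groups")
    a = expr[labels.index[labels == groups[0]]].to_numpy(dtype=float)
    b = expr[labels.index[labels == groups[1]]].to_numpy(dtype=float)
    logfc = a.mean(axis=1) - b.mean(axis=1)
    pvals = np.array([wilcoxon_rank_sum(a[i], b[i])[1] for i in range(expr.shape[0])])
    fdr = bh_fdr(pvals)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "p": pvals,
            "fdr": fdr,
            "flag": (np.abs(logfc) > logfc_thresh) & (fdr < alpha),
        },
        index=expr.index,
    )


def _corr_with_p(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-by-column Pearson r and two-sided t p between x (f x n) and y (n x c)."""
    n = x.shape[1]
    xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    ys = (y - y.mean(axis=0, keepdims=True)) / y.std(axis=0, keepdims=True)
    r = xs @ ys / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(p), 0.0, p)  # |r| == 1
    return r, p


def infiltration_correlation(
    expr: pd.DataFrame,
    prom_meth: pd.DataFrame,
    infiltration: pd.DataFrame,
    lncrnas: list[str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Immune-related lncRNA filter against immune-cell infiltration.

    For every (lncRNA, cell type) pair, Pearson correlations are
    computed at the expression and at the methylation level; BH-FDR is
    applied across the full pair grid within each level. A pair passes
    when both q-values are below *alpha* and the two correlations have
    strictly opposite signs. Returns the long-format pair table and a
    per-lncRNA summary with ``n_cells_passed``.
    """
    shared = expr.columns.intersection(prom_meth.columns).intersection(infiltration.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples")
    lncrnas = [g for g in lncrnas if g in expr.index and g in prom_meth.index]
    e = expr.loc[lncrnas, shared].to_numpy(dtype=float)
    m = prom_meth.loc[lncrnas, shared].to_numpy(dtype=float)
    infil = infiltration.loc[shared].to_numpy(dtype=float)

    r_e, p_e = _corr_with_p(e, infil)
    r_m, p_m = _corr_with_p(m, infil)
    q_e = bh_fdr(p_e.ravel()).reshape(p_e.shape)
    q_m = bh_fdr(p_m.ravel()).reshape(p_m.shape)

    cells = list(infiltration.columns)
    pairs = pd.DataFrame(
        {
            "lncrna": np.repeat(lncrnas, len(cells)),
            "cell_type": np.tile(cells, len(lncrnas)),
            "r_expr": r_e.ravel(),
            "q_expr": q_e.ravel(),
            "r_meth": r_m.ravel(),
            "q_meth": q_m.ravel(),
        }
    )
    pairs["passed"] = (
        (pairs["q_expr"] < alpha)
        & (pairs["q_meth"] < alpha)
        & (np.sign(pairs["r_expr"]) == -np.sign(pairs["r_meth"]))
        & (pairs["r_expr"] != 0)
    )
    verdict = (
        pairs.groupby("lncrna", sort=False)["passed"].sum().astype(int).rename("n_cells_passed").to_frame()
    )
    return pairs, verdict


def partial_correlation(x, y, z) -> float:
    """First-order partial correlation of x and y controlling for z."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (len(x) == len(y) == len(z)) or len(x) < 4:
        raise ValueError("vectors must share a length >= 4")
    for v in (x, y, z):
        if np.ptp(v) == 0:
            raise ValueError("constant vector")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if min(1.0 - abs(r_xz), 1.0 - abs(r_yz)) < 1e-12:
        raise ValueError("control variable collinear with an input")
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    return float((r_xy - r_xz * r_yz) / np.sqrt(denom))


def gsea_es(
    ranked: list[str], weights, gene_set: set[str], p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov-Smirnov enrichment of *gene_set* in *ranked*.

    Hits increment the running sum proportionally to ``|weight|**p``,
    misses decrement by ``1 / (n - |S|)``; the enrichment score is the
    running-sum extremum of largest magnitude (signed).
    """
    n = len(ranked)
    w = np.abs(np.asarray(weights, dtype=float)) ** p
    hit = np.fromiter((g in gene_set for g in ranked), dtype=bool, count=n)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has no member in the ranking")
    if n_hit == n:
        raise ValueError("gene set covers the whole ranking")
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit weights zero: fall back to unweighted steps
        hit_w = hit.astype(float)
        total = float(n_hit)
    running = np.cumsum(hit_w / total - (~hit) / (n - n_hit))
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def _null_es(w_abs: np.ndarray, n_hit: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Permutation null: enrichment scores of random size-n_hit hit sets."""
    n = w_abs.size
    u = rng.random((n_perm, n))
    hit_idx = np.argpartition(u, n_hit - 1, axis=1)[:, :n_hit]
    rows = np.repeat(np.arange(n_perm), n_hit)
    hit_mask = np.zeros((n_perm, n))
    hit_mask[rows, hit_idx.ravel()] = 1.0
    hit_w = hit_mask * w_abs[None, :]
    totals = hit_w.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        hit_w[zero] = hit_mask[zero]
        totals = hit_w.sum(axis=1, keepdims=True)
    miss = (1.0 - hit_mask) / (n - n_hit)
    running = np.cumsum(hit_w / totals - miss, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), idx]


def lncrna_pathway_association(
    expr: pd.DataFrame,
    lncrna_id: str,
    pathways: dict[str, set[str]],
    purity: pd.Series,
    pcg_ids: list[str] | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """Purity-adjusted partial-correlation GSEA of a lncRNA against pathways.

    All protein-coding genes are ranked by their partial correlation
    with the lncRNA (controlling for tumor purity), descending; each
    pathway's enrichment score in that ranking is compared with a
    gene-label permutation null of *n_perm* draws (add-one smoothed
    p-value), and BH-FDR is applied across pathways.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if lncrna_id not in expr.index:
        raise KeyError(lncrna_id)
    if pcg_ids is None:
        pcg_ids = [g for g in expr.index if g != lncrna_id]
    pcg_ids = [g for g in pcg_ids if g != lncrna_id and g in expr.index]
    if len(pcg_ids) < 10:
        raise ValueError("need at least 10 protein-coding genes")
    shared = expr.columns.intersection(purity.index)
    lnc = expr.loc[lncrna_id, shared].to_numpy(dtype=float)
    z = purity.loc[shared].to_numpy(dtype=float)

    pcors = {}
    for g in pcg_ids:
        try:
            pcors[g] = partial_correlation(expr.loc[g, shared].to_numpy(dtype=float), lnc, z)
        except ValueError:
            continue
    if len(pcors) < 10:
        raise ValueError(
            "partial correlation undefined for almost all genes "
            "(is the purity control variable constant?)"
        )
    ranking = sorted(pcors, key=lambda g: (-pcors[g], g))
    weights = np.array([pcors[g] for g in ranking])
    w_abs = np.abs(weights) ** weight_p

    rng = np.random.default_rng(seed)
    rows = []
    for name in sorted(pathways):
        members = pathways[name] & set(ranking)
        if not members or len(members) == len(ranking):
            continue
        es, _ = gsea_es(ranking, weights, members, p=weight_p)
        null = _null_es(w_abs, len(members), n_perm, rng)
        p_perm = (1.0 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1.0)
        null_side = null[np.sign(null) == np.sign(es)] if es != 0 else null
        mean_mag = np.mean(np.abs(null_side)) if null_side.size else np.mean(np.abs(null))
        nes = es / mean_mag if mean_mag > 0 else 0.0
        rows.append({"lncrna": lncrna_id, "pathway": name, "es": es, "nes": nes, "p_perm": p_perm})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = bh_fdr(out["p_perm"].to_numpy())
    return out
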