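"""Consensus-clustering subtype discovery on lncRNA promoter methylation.

The stage mirrors resampling-based consensus clustering: repeatedly
subsample the cohort, cluster each subsample, and summarize co-clustering
frequencies into a consensus matrix per candidate k; the number of
clusters is chosen by the PAC criterion (proportion of ambiguous
consensus entries). Feature selection keeps the most variable promoters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "select_variable_features",
    "consensus_cluster",
    "select_k",
    "filter_small_clusters",
    "pac",
    "ConsensusResult",
    "SubtypeResult",
    "UNASSIGNED",
]

UNASSIGNED = -1


@dataclass
class ConsensusResult:
    k: int
    consensus: pd.DataFrame  # sample x sample, in [0, 1]
    labels: pd.Series  # sample -> 1..k
    n_iter: int
    subsample_frac: float
    seed: int


@dataclass
class SubtypeResult:
    chosen_k: int
    labels: pd.Series
    per_k_stats: dict[int, dict] = field(default_factory=dict)


def select_variable_features(prom_meth: pd.DataFrame, fraction: float = 0.05) -> list[str]:
    """Top ``ceil(fraction * n)`` features by cross-sample standard deviation.

    Missing values are ignored per feature; all-missing features are
    excluded before ranking. Ties at the cutoff break lexicographically
    by feature id so the selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    sd = prom_meth.std(axis=1, ddof=1, skipna=True).dropna()
    n_keep = int(np.ceil(fraction * len(sd)))
    order = sorted(sd.index, key=lambda g: (-sd[g], g))
    return order[:n_keep]


def _impute_mean(matrix: pd.DataFrame) -> np.ndarray:
    x = matrix.to_numpy(dtype=float)
    row_mean = np.nanmean(x, axis=1, keepdims=True)
    return np.where(np.isnan(x), row_mean, x)


def _cluster_columns(x: np.ndarray, k: int) -> np.ndarray:
    """Agglomerative average-linkage clustering of the columns.

    Euclidean distance on the beta values: subtype structure in promoter
    methylation is predominantly a shared shift of the selected features
    in one direction (hypo- vs hypermethylation), which profile-shape
    metrics such as 1 - Pearson cancel out but Euclidean distance sees
    directly.
    """
    z = linkage(x.T, method="average", metric="euclidean")
    return fcluster(z, t=k, criterion="maxclust")


def consensus_cluster(
    matrix: pd.DataFrame,
    k: int,
    n_iter: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Resampled co-clustering consensus for a fixed k.

    *matrix* is features x samples. Each iteration draws
    ``floor(subsample_frac * n)`` samples without replacement using a
    counter-based stream (iteration i is seeded by ``(seed, i)``, so
    raising ``n_iter`` never reshuffles earlier iterations), clusters
    them, and accumulates co-cluster / co-sample counts. Pairs never
    co-sampled get consensus 0 with a warning. Final labels come from
    average-linkage hierarchical clustering of ``1 - consensus`` cut at k.
    """
    n = matrix.shape[1]
    if k < 2:
        raise ValueError("k must be >= 2")
    n_sub = int(np.floor(subsample_frac * n))
    if n_sub < k:
        raise ValueError("subsample smaller than k")
    x = _impute_mean(matrix)

    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for it in range(n_iter):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(it,)))
        idx = rng.choice(n, size=n_sub, replace=False)
        lab = _cluster_columns(x[:, idx], k)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        co_sample[np.ix_(idx, idx)] += 1.0
        same = lab[:, None] == lab[None, :]
        co_cluster[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
    if (co_sample == 0).any():
        warnings.warn("some sample pairs were never co-sampled; consensus set to 0")
    consensus = (consensus + consensus.T) / 2.0
    np.fill_diagonal(consensus, np.where(np.diag(co_sample) > 0, 1.0, 0.0))

    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    cons_df = pd.DataFrame(consensus, index=matrix.columns, columns=matrix.columns)
    return ConsensusResult(
        k=k,
        consensus=cons_df,
        labels=pd.Series(labels, index=matrix.columns, name="cluster"),
        n_iter=n_iter,
        subsample_frac=subsample_frac,
        seed=seed,
    )


def pac(consensus: pd.DataFrame, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: off-diagonal consensus in (lower, upper)."""
    c = consensus.to_numpy()
    iu = np.triu_indices_from(c, k=1)
    vals = c[iu]
    return float(np.mean((vals > lower) & (vals < upper)))


def select_k(results: list[ConsensusResult]) -> SubtypeResult:
    """Pick the candidate k with minimal PAC (ties -> smallest k)."""
    if len(results) < 2:
        raise ValueError("need at least two candidate k values")
    stats = {}
    for res in results:
        stats[res.k] = {
            "pac": pac(res.consensus),
            "mean_consensus": float(res.consensus.to_numpy()[np.triu_indices(len(res.consensus), 1)].mean()),
        }
    chosen = min(stats, key=lambda k: (round(stats[k]["pac"], 12), k))
    best = next(r for r in results if r.k == chosen)
    return SubtypeResult(chosen_k=chosen, labels=best.labels.copy(), per_k_stats=stats)


def filter_small_clusters(labels: pd.Series, min_size: int = 5) -> pd.Series:
    """Drop clusters of size <= min_size; their samples become UNASSIGNED.

    Retention is strict: a cluster survives only with *more than*
    ``min_size`` members. If nothing survives, raise.
    """
    if labels.empty:
        raise ValueError("labels are empty")
    sizes = labels.value_counts()
    keep = set(sizes.index[sizes > min_size])
    if not keep:
        raise ValueError("all clusters fall below the minimum size")
    out = labels.copy()
    out[~labels.isin(keep)] = UNASSIGNED
    return out
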