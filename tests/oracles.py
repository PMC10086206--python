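"""Independent brute-force oracles used to cross-check the implementation.

Each oracle restates the target quantity from its definition with plain
loops, sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def interval_mapping_oracle(probes, genes, half_window):
    """O(probes x genes) membership test: {gene: set of probe ids}."""
    out = {}
    for gene_id, gene in genes.iterrows():
        hits = set()
        for probe_id, probe in probes.iterrows():
            if probe.chrom == gene.chrom and (
                gene.tss - half_window <= probe.pos < gene.tss + half_window
            ):
                hits.add(probe_id)
        if hits:
            out[gene_id] = hits
    return out


def ssgsea_oracle(values, gene_ids, gene_set, alpha=0.25):
    """Step-by-step weighted/unweighted ECDF difference."""
    order = sorted(range(len(gene_ids)), key=lambda i: (-values[i], gene_ids[i]))
    n = len(order)
    in_flags = [gene_ids[i] in gene_set for i in order]
    ranks = list(range(n, 0, -1))
    denom_in = sum(abs(ranks[pos]) ** alpha for pos in range(n) if in_flags[pos])
    n_out = n - sum(in_flags)
    score = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for pos in range(n):
        if in_flags[pos]:
            cum_in += abs(ranks[pos]) ** alpha / denom_in
        else:
            cum_out += 1.0 / n_out
        score += cum_in - cum_out
    return score


def gsea_es_oracle(ranked, weights, gene_set, p=1.0):
    """Running-sum extremum computed with an explicit loop."""
    n = len(ranked)
    hits = [g in gene_set for g in ranked]
    denom = sum(abs(w) ** p for w, h in zip(weights, hits) if h)
    n_out = n - sum(hits)
    running = []
    s = 0.0
    for g, w, h in zip(ranked, weights, hits):
        if h:
            s += (abs(w) ** p / denom) if denom > 0 else 1.0 / sum(hits)
        else:
            s -= 1.0 / n_out
        running.append(s)
    extremum = max(running, key=abs)
    return extremum


def bh_oracle(p):
    """Step-up from the definition: q_(i) = min_{j>=i} p_(j) * n / j."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [None] * n
    for pos, i in enumerate(order):
        candidates = [p[order[j]] * n / (j + 1) for j in range(pos, n)]
        q[i] = min(1.0, min(candidates))
    return np.array(q)


def km_oracle(times, events):
    """Product-limit estimate looped over distinct times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out = []
    s = 1.0
    for t in np.unique(times):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        if at_risk > 0:
            s *= 1.0 - d / at_risk
        out.append((float(t), at_risk, d, s))
    return out


def partial_corr_oracle(x, y, z):
    """Correlate the residuals of x|z and y|z (least-squares with intercept)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    design = np.column_stack([np.ones_like(z), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])
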