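"""Input/output and promoter-level methylation summaries.

All tabular structures are pandas objects with documented schemas:

- probe annotation: DataFrame indexed by ``probe_id`` with columns
  ``chrom`` (str) and ``pos`` (1-based int).
- gene annotation: DataFrame indexed by ``gene_id`` with columns
  ``biotype`` ("lncRNA" / "PCG"), ``chrom``, ``strand`` ("+" / "-") and
  ``tss`` (1-based int; already strand-resolved).
- methylation matrix: DataFrame (probes x samples) of beta values in
  [0, 1], NaN for missing.
- promoter methylation matrix: DataFrame (genes x samples) of averaged
  betas, with the per-gene probe count in ``df.attrs["n_probes"]``.
- expression matrix: DataFrame (genes x samples) of non-negative
  log2-scale values.

Every interval in this package is half-open ``[start, end)``; the 4-kb
promoter of a gene is ``[tss - half_window, tss + half_window)``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "map_probes_to_promoters",
    "promoter_beta",
    "chromatin_state_beta",
    "read_gmt",
    "write_gmt",
    "read_matrix",
    "write_matrix",
    "validate_beta_matrix",
]

CHROMATIN_STATES = tuple(f"E{i:02d}" for i in range(1, 19))


def validate_beta_matrix(meth: pd.DataFrame) -> None:
    """Raise ValueError if *meth* is not a valid beta matrix."""
    if meth.index.has_duplicates or meth.columns.has_duplicates:
        raise ValueError("beta matrix row/column labels must be unique")
    vals = meth.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("beta values must lie in [0, 1]")


def map_probes_to_promoters(
    probes: pd.DataFrame,
    genes: pd.DataFrame,
    half_window: int = 2000,
) -> dict[str, set[str]]:
    """Map 450K probes into promoter windows centered at each gene's TSS.

    A probe maps to a gene iff it is on the same chromosome and its
    position lies in ``[tss - half_window, tss + half_window)``. A probe
    may serve several promoters; genes without any probe are absent from
    the result.
    """
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    known = set(probes["chrom"]) & set(genes["chrom"])
    orphan_p = set(probes["chrom"]) - known
    orphan_g = set(genes["chrom"]) - known
    if orphan_p or orphan_g:
        warnings.warn(
            f"chromosomes without counterpart skipped: probes={sorted(orphan_p)}, "
            f"genes={sorted(orphan_g)}"
        )

    mapping: dict[str, set[str]] = {}
    probes_by_chrom = {
        chrom: sub.sort_values("pos") for chrom, sub in probes.groupby("chrom")
    }
    for gene_id, gene in genes.iterrows():
        sub = probes_by_chrom.get(gene.chrom)
        if sub is None:
            continue
        lo = np.searchsorted(sub["pos"].to_numpy(), gene.tss - half_window, "left")
        hi = np.searchsorted(sub["pos"].to_numpy(), gene.tss + half_window, "left")
        if hi > lo:
            mapping[str(gene_id)] = set(sub.index[lo:hi])
    return mapping


def promoter_beta(
    meth: pd.DataFrame, mapping: dict[str, set[str]]
) -> pd.DataFrame:
    """Average probe betas into gene-level promoter methylation.

    The (gene, sample) entry is the arithmetic mean over the gene's
    non-missing probe betas; it is NaN only when every probe is missing.
    Genes whose probe set is empty are dropped with a warning.
    """
    rows = {}
    n_probes = {}
    probe_index = meth.index
    for gene_id, probe_ids in mapping.items():
        present = probe_index.intersection(sorted(probe_ids))
        if len(present) == 0:
            warnings.warn(f"gene {gene_id} has no probes in the beta matrix; dropped")
            continue
        missing = set(probe_ids) - set(present)
        if missing:
            raise KeyError(f"probes absent from beta matrix: {sorted(missing)[:5]}")
        rows[gene_id] = meth.loc[present].mean(axis=0, skipna=True)
        n_probes[gene_id] = len(present)
    out = pd.DataFrame(rows).T
    out.columns = meth.columns
    out.attrs["n_probes"] = pd.Series(n_probes, dtype=int)
    return out


def chromatin_state_beta(
    meth: pd.DataFrame,
    probes: pd.DataFrame,
    segments: pd.DataFrame,
) -> pd.DataFrame:
    """Average probe betas within ChromHMM-style chromatin states.

    *segments* is BED-like: columns ``chrom``, ``start``, ``end``,
    ``state`` with half-open [start, end) intervals and states from the
    18-label Roadmap alphabet. A probe falling in no segment is ignored;
    a state covering no probe yields an all-NaN row.
    """
    bad = set(segments["state"]) - set(CHROMATIN_STATES)
    if bad:
        raise ValueError(f"unknown chromatin states: {sorted(bad)}")
    if (segments["start"] >= segments["end"]).any():
        raise ValueError("segment start must be < end")

    probe_state: dict[str, str] = {}
    for chrom, seg in segments.groupby("chrom"):
        sub = probes[probes["chrom"] == chrom]
        if sub.empty:
            continue
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        states = seg["state"].to_numpy()
        pos = sub["pos"].to_numpy()
        for pid, p in zip(sub.index, pos):
            inside = (starts <= p) & (p < ends)
            if inside.any():
                probe_state[pid] = states[np.argmax(inside)]

    out = pd.DataFrame(
        np.nan, index=sorted(set(segments["state"])), columns=meth.columns
    )
    assigned = pd.Series(probe_state)
    for state in out.index:
        pids = assigned.index[assigned == state]
        pids = meth.index.intersection(pids)
        if len(pids):
            out.loc[state] = meth.loc[pids].mean(axis=0, skipna=True)
    return out


# ---------------------------------------------------------------------------
# plumbing: GMT gene sets and TSV matrices


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file into ``{set_name: member set}``.

    Line format: name <tab> description <tab> member1 <tab> member2 ...
    Duplicate set names and empty member lists are errors.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p for p in parts[2:]):
                raise ValueError(f"{path}:{lineno}: gene set with no members")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = {p for p in parts[2:] if p}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_matrix(path) -> pd.DataFrame:
    """Read a TSV matrix: header row = sample ids, first column = features."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)
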