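#!/usr/bin/env python
"""Immune landscape of the subtypes and immune-related lncRNA calling.

Scores every sample for immune signatures (ssGSEA), cytolytic activity,
MHC-I expression and an ESTIMATE-like purity surrogate; runs
differential expression between subtypes; filters ER lncRNAs by
opposite-direction infiltration correlations; and links the resulting
immune lncRNAs to immune pathways by purity-adjusted partial-correlation
GSEA (1000 permutations).
"""

from pathlib import Path

import pandas as pd

from epilnc import er as er_mod, immune, io_annotation as ioa
from epilnc.pipeline import stage_seed

ROOT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 7) -> None:
    cohort_dir = ROOT / "cohort"
    expr = ioa.read_matrix(cohort_dir / "expression.tsv")
    genes = ioa.read_matrix(cohort_dir / "genes.tsv")
    infil = ioa.read_matrix(cohort_dir / "infiltration.tsv")
    prom = ioa.read_matrix(ROOT / "promoter_beta.tsv")
    labels = pd.read_csv(ROOT / "subtypes.tsv", sep="\t", index_col=0)["cluster"]
    er_table = pd.read_csv(ROOT / "er_records.tsv", sep="\t", index_col=0)
    er_ids = sorted(er_table.index[er_table["is_er"]])

    signatures = ioa.read_gmt(cohort_dir / "signatures.gmt")
    pathways = ioa.read_gmt(cohort_dir / "pathways.gmt")
    est_sets = ioa.read_gmt(cohort_dir / "estimate.gmt")
    mhc1 = next(iter(ioa.read_gmt(cohort_dir / "mhc1.gmt").values()))

    scores = immune.signature_scores(expr, signatures)
    scores["CYT"] = immune.cyt_score(expr)
    scores["MHC"] = immune.mhc_score(expr, mhc1)
    est = immune.estimate_like(expr, est_sets["STROMAL"], est_sets["IMMUNE"])
    scores = scores.join(est)
    scores.to_csv(ROOT / "immune_scores.tsv", sep="\t")
    hot = labels.index[labels == 1]
    cold = labels.index[labels == 2]
    for name in ("IFN_gamma_response", "CYT", "MHC", "combined"):
        _, p = er_mod.wilcoxon_rank_sum(scores.loc[hot, name], scores.loc[cold, name])
        print(f"{name}: hot mean {scores.loc[hot, name].mean():.3f} vs "
              f"cold {scores.loc[cold, name].mean():.3f} (Wilcoxon p = {p:.2e})")

    pcg_ids = [g for g in expr.index if genes.loc[g, "biotype"] == "PCG"]
    de = immune.differential_expression(expr.loc[pcg_ids], labels)
    de.to_csv(ROOT / "differential_expression.tsv", sep="\t")
    print(f"{int(de['flag'].sum())} of {len(de)} PCGs differentially expressed "
          f"(|logFC| > 0.75, FDR < 0.05)")

    lnc_prom = prom.loc[[g for g in prom.index if genes.loc[g, "biotype"] == "lncRNA"]]
    pairs, verdicts = immune.infiltration_correlation(expr, lnc_prom, infil, er_ids)
    pairs.to_csv(ROOT / "infiltration_pairs.tsv", sep="\t", index=False)
    immune_lncs = sorted(verdicts.index[verdicts["n_cells_passed"] >= 4])
    print(f"{len(immune_lncs)} immune-related lncRNAs "
          f"(opposite-direction rule in >= 4 of {infil.shape[1]} cell types)")

    purity = immune.purity_from_estimate(est["combined"])
    tables = []
    for lnc in immune_lncs[:10]:
        tables.append(immune.lncrna_pathway_association(
            expr, lnc, pathways, purity, pcg_ids=pcg_ids,
            n_perm=1000, seed=stage_seed(seed, lnc)))
    if tables:
        assoc = pd.concat(tables, ignore_index=True)
        assoc.to_csv(ROOT / "pathway_associations.tsv", sep="\t", index=False)
        hits = assoc[(assoc["fdr"] < 0.05) & (assoc["es"] > 0)]
        print(f"{len(hits)} significant positive lncRNA-pathway links "
              f"across {assoc['lncrna'].nunique()} lncRNAs")
        pd.Series(sorted(immune_lncs), name="lncrna").to_csv(
            ROOT / "immune_lncrnas.txt", index=False, header=False)


if __name__ == "__main__":
    main()
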