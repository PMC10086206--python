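#!/usr/bin/env python
"""Survival value of the methylation subtypes.

Kaplan-Meier / log-rank comparison of the two subtypes, the
likelihood-ratio ladder of clinical features over an age+gender base
Cox model, bidirectional stepwise-AIC selection, TMB by subtype and
hypergeometric enrichment of subtypes against tumor grade.
"""

from pathlib import Path

import pandas as pd

from epilnc import io_annotation as ioa, survival as sv

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    clinical = pd.read_csv(ROOT / "cohort" / "clinical.tsv", sep="\t", index_col=0)
    labels = pd.read_csv(ROOT / "subtypes.tsv", sep="\t", index_col=0)["cluster"]
    clin = clinical.loc[labels.index].copy()
    clin["subtype"] = labels.astype(str)

    for c in sorted(labels.unique()):
        km = sv.km_estimate(clin[clin["subtype"] == str(c)])
        km.to_csv(ROOT / f"km_cluster{c}.tsv", sep="\t", index=False)
    chi2, p = sv.logrank_test(clin, clin["subtype"])
    print(f"log-rank subtype 1 vs 2: chi2 = {chi2:.2f}, p = {p:.2e}")

    ladder = sv.lr_ladder(clin, ["grade", "subtype"])
    ladder.to_csv(ROOT / "lr_ladder.tsv", sep="\t")
    best = ladder["lr"].idxmax()
    print("LR gain over age+gender base model: "
          + ", ".join(f"{f}: {ladder.loc[f, 'lr']:.2f} (p={ladder.loc[f, 'p']:.2e})"
                      for f in ladder.index)
          + f"; best fit improvement from '{best}'")

    selected, fit = sv.stepwise_cox(clin, ["age", "grade", "subtype", "gender"])
    print(f"stepwise-AIC Cox selected: {', '.join(selected) or 'none'}"
          + (f" (AIC {fit.aic:.1f})" if fit else ""))

    tmb = sv.compute_tmb(clin["mutation_count"])
    by = tmb.groupby(clin["subtype"]).mean()
    print("TMB (mut/Mb) by subtype: "
          + ", ".join(f"{c}: {v:.2f}" for c, v in by.items()))

    enrich = sv.hypergeometric_enrichment(clin["subtype"], clin["grade"])
    enrich.to_csv(ROOT / "grade_enrichment.tsv", sep="\t")


if __name__ == "__main__":
    main()
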