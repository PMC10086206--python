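#!/usr/bin/env python
"""Immune-evasion readouts for the immune-related ER lncRNAs.

Correlates immune lncRNA expression with the immunosuppressive marker
set, tests responder vs non-responder expression differences, and
compares promoter methylation against expression as median-split
Kaplan-Meier prognostic readouts.
"""

from pathlib import Path

import pandas as pd

from epilnc import evasion, io_annotation as ioa

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort_dir = ROOT / "cohort"
    expr = ioa.read_matrix(cohort_dir / "expression.tsv")
    prom = ioa.read_matrix(ROOT / "promoter_beta.tsv")
    clinical = pd.read_csv(cohort_dir / "clinical.tsv", sep="\t", index_col=0)
    response = pd.read_csv(cohort_dir / "response.tsv", sep="\t", index_col=0)["response"]
    markers = next(iter(ioa.read_gmt(cohort_dir / "markers.gmt").values()))
    lncs = pd.read_csv(ROOT / "immune_lncrnas.txt", header=None)[0].tolist()

    marker_tab = evasion.marker_correlation(
        expr.loc[lncs], expr.loc[expr.index.intersection(sorted(markers))]
    )
    marker_tab.to_csv(ROOT / "marker_correlations.tsv", sep="\t", index=False)
    sig = marker_tab[marker_tab["q"] < 0.05]
    print(f"{len(sig)}/{len(marker_tab)} lncRNA-marker pairs significant "
          f"(median r among significant {sig['r'].median():.2f})")

    resp = evasion.response_association(expr.loc[lncs], response)
    resp.to_csv(ROOT / "response_association.tsv", sep="\t")
    down = (resp["direction"] == "down_in_responders").sum()
    print(f"{down}/{len(resp)} immune lncRNAs significantly decreased in "
          f"immunotherapy responders")

    prog = evasion.prognosis_comparison(prom, expr, clinical, lncs)
    prog.to_csv(ROOT / "prognosis_comparison.tsv", sep="\t")
    meth_wins = (prog["better"] == "methylation").sum()
    print(f"methylation beats expression as a prognostic split for "
          f"{meth_wins}/{len(prog)} immune lncRNAs")


if __name__ == "__main__":
    main()
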