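"""Immune-evasion association of immune-related ER lncRNAs.

Correlates lncRNA expression with immunosuppressive marker genes,
tests lncRNA expression between immunotherapy responders and
non-responders, and compares promoter methylation against expression as
prognostic readouts via median-split Kaplan-Meier log-rank tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .er import bh_fdr, pearson, wilcoxon_rank_sum
from .survival import logrank_test

__all__ = ["marker_correlation", "response_association", "prognosis_comparison"]


def marker_correlation(
    lnc_expr: pd.DataFrame, marker_expr: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of every (lncRNA, marker) pair with grid-wide BH-FDR.

    Constant markers are excluded; the FDR correction runs across the
    full pair grid, not per marker.
    """
    shared = lnc_expr.columns.intersection(marker_expr.columns)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples")
    rows = []
    for lnc in lnc_expr.index:
        x = lnc_expr.loc[lnc, shared].to_numpy(dtype=float)
        for marker in marker_expr.index:
            y = marker_expr.loc[marker, shared].to_numpy(dtype=float)
            try:
                r, p = pearson(x, y)
            except ValueError:
                continue
            rows.append((lnc, marker, r, p))
    out = pd.DataFrame(rows, columns=["lncrna", "marker", "r", "p"])
    if not out.empty:
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def response_association(
    lnc_expr: pd.DataFrame, response_labels: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Wilcoxon test of each lncRNA between responders and non-responders.

    ``direction`` is the sign of the responder-minus-non-responder
    median difference ("down_in_responders" / "up_in_responders"), or
    "ns" when p >= alpha.
    """
    shared = lnc_expr.columns.intersection(response_labels.index)
    labels = response_labels.loc[shared]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("need exactly two response classes")
    resp = shared[(labels == "responder").to_numpy()]
    nonresp = shared[(labels != "responder").to_numpy()]
    if len(resp) == 0 or len(nonresp) == 0:
        raise ValueError("both response classes must be non-empty")
    rows = []
    for lnc in lnc_expr.index:
        a = lnc_expr.loc[lnc, resp].to_numpy(dtype=float)
        b = lnc_expr.loc[lnc, nonresp].to_numpy(dtype=float)
        _, p = wilcoxon_rank_sum(a, b)
        diff = np.median(a) - np.median(b)
        if p >= alpha:
            direction = "ns"
        else:
            direction = "down_in_responders" if diff < 0 else "up_in_responders"
        rows.append((lnc, p, diff, direction))
    return pd.DataFrame(
        rows, columns=["lncrna", "p", "median_diff", "direction"]
    ).set_index("lncrna")


def _median_split_logrank(values: pd.Series, survival: pd.DataFrame) -> float:
    """Log-rank p of the median split of *values*; NaN on a degenerate split."""
    med = values.median()
    groups = pd.Series(np.where(values > med, "high", "low"), index=values.index)
    if groups.nunique() < 2:
        return float("nan")
    _, p = logrank_test(survival.loc[values.index], groups)
    return p


def prognosis_comparison(
    prom_meth: pd.DataFrame,
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    lncrnas: list[str],
) -> pd.DataFrame:
    """Methylation vs expression as a prognostic readout per lncRNA.

    Samples are median-split by promoter methylation and, separately, by
    expression; each split is scored by a log-rank test and ``better``
    names the level with the smaller p (splits identical up to a
    monotone transform give equal p-values).
    """
    shared = prom_meth.columns.intersection(expr.columns).intersection(survival.index)
    rows = []
    for lnc in lncrnas:
        p_meth = _median_split_logrank(prom_meth.loc[lnc, shared], survival)
        p_expr = _median_split_logrank(expr.loc[lnc, shared], survival)
        if np.isnan(p_meth) and np.isnan(p_expr):
            better = "neither"
        elif np.isnan(p_expr) or p_meth < p_expr:
            better = "methylation"
        elif np.isnan(p_meth) or p_expr < p_meth:
            better = "expression"
        else:
            better = "tie"
        rows.append((lnc, p_meth, p_expr, better))
    return pd.DataFrame(
        rows, columns=["lncrna", "km_p_meth", "km_p_expr", "better"]
    ).set_index("lncrna")
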