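"""Survival analysis and model-comparison machinery.

Kaplan-Meier estimation, the log-rank test and Cox proportional-hazards
fitting (Efron tie handling) are delegated to lifelines behind this
module's surface; the likelihood-ratio feature ladder, the stepwise-AIC
Cox selection, tumor mutational burden and the hypergeometric
subtype-enrichment test are implemented here.

Survival records are a DataFrame indexed by sample id with ``time``
(non-negative), ``event`` (1 = death) and arbitrary covariate columns;
categorical covariates are dummy-encoded (first level dropped, levels
sorted) before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "null_loglik",
    "lr_ladder",
    "stepwise_cox",
    "compute_tmb",
    "hypergeometric_enrichment",
]


@dataclass
class CoxFit:
    coefficients: dict[str, float]
    loglik: float
    n_events: int
    converged: bool
    n_params: int = 0

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


def _check_records(records: pd.DataFrame) -> None:
    if len(records) == 0:
        raise ValueError("no survival records")
    if (records["time"] < 0).any():
        raise ValueError("negative survival time")


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event/censoring time with ``at_risk``,
    ``observed`` (events) and ``survival``. Subjects censored at t are
    still at risk for the events at t.
    """
    _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    table = kmf.event_table
    observed_times = set(records["time"])
    keep = [t in observed_times for t in table.index]  # drop lifelines' synthetic t=0 row
    table = table[keep]
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index)
    return pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "observed": table["observed"].to_numpy(dtype=int),
            "survival": surv.to_numpy(dtype=float),
        }
    ).reset_index(drop=True)


def logrank_test(records: pd.DataFrame, group_labels: pd.Series) -> tuple[float, float]:
    """Multigroup log-rank chi-square test (df = groups − 1)."""
    _check_records(records)
    groups = group_labels.loc[records.index]
    if groups.nunique() < 2:
        raise ValueError("need at least two groups")
    if records["event"].sum() < 1:
        raise ValueError("need at least one event")
    res = multivariate_logrank_test(records["time"], groups, records["event"])
    return float(res.test_statistic), float(res.p_value)


def _design(records: pd.DataFrame, covariate_names: list[str]) -> pd.DataFrame:
    cols = []
    for name in covariate_names:
        col = records[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).astype(float).rename(f"{name}[{lev}]"))
        else:
            cols.append(col.astype(float))
    return pd.concat(cols, axis=1)


def cox_fit(records: pd.DataFrame, covariate_names: list[str]) -> CoxFit:
    """Cox proportional hazards fit (Efron ties, Newton iterations)."""
    _check_records(records)
    if records["event"].sum() < 1:
        raise ValueError("need at least one event")
    x = _design(records, covariate_names)
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise ValueError("collinear covariates")
    df = pd.concat([records[["time", "event"]], x], axis=1)
    cph = CoxPHFitter(penalizer=0.0)
    try:
        cph.fit(df, duration_col="time", event_col="event")
        converged = True
        coefs = cph.params_.to_dict()
        ll = float(cph.log_likelihood_)
    except ConvergenceError:
        return CoxFit({}, float("nan"), int(records["event"].sum()), False, x.shape[1])
    return CoxFit(coefs, ll, int(records["event"].sum()), converged, x.shape[1])


def null_loglik(records: pd.DataFrame) -> float:
    """Efron partial log-likelihood of the covariate-free Cox model.

    With all relative hazards equal to 1, an event time with d tied
    events and risk-set size r contributes −Σ_{j<d} log(r − j).
    """
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=int)
    ll = 0.0
    for et in np.unique(t[e == 1]):
        d = int(np.sum((t == et) & (e == 1)))
        r = int(np.sum(t >= et))
        ll -= sum(np.log(r - j) for j in range(d))
    return ll


def _rank_increases(base: pd.DataFrame, extra: pd.DataFrame) -> bool:
    if base.shape[1] == 0:
        return np.linalg.matrix_rank(extra.to_numpy()) == extra.shape[1]
    joint = np.hstack([base.to_numpy(), extra.to_numpy()])
    return np.linalg.matrix_rank(joint) == np.linalg.matrix_rank(base.to_numpy()) + extra.shape[1]


def lr_ladder(
    records: pd.DataFrame,
    candidate_features: list[str],
    base_covariates: tuple[str, ...] = ("age", "gender"),
) -> pd.DataFrame:
    """Likelihood-ratio gain of each feature over a fixed base model.

    Each candidate is added alone to the base Cox model (age + gender by
    default); LR = 2·(ll(base + f) − ll(base)) with a chi-square p at
    df = parameters added. A candidate collinear with the base design
    (e.g. a duplicated covariate) contributes exactly LR = 0.
    """
    base_fit = cox_fit(records, list(base_covariates))
    if not base_fit.converged:
        raise RuntimeError("base model did not converge")
    base_x = _design(records, list(base_covariates))
    rows = []
    for f in candidate_features:
        extra = _design(records, [f])
        df_added = extra.shape[1]
        if not _rank_increases(base_x, extra):
            rows.append((f, 0.0, 1.0, df_added))
            continue
        full = cox_fit(records, list(base_covariates) + [f])
        if not full.converged:
            rows.append((f, float("nan"), float("nan"), df_added))
            continue
        lr = 2.0 * (full.loglik - base_fit.loglik)
        rows.append((f, lr, float(stats.chi2.sf(max(lr, 0.0), df=df_added)), df_added))
    return pd.DataFrame(rows, columns=["feature", "lr", "p", "df"]).set_index("feature")


def stepwise_cox(
    records: pd.DataFrame, features: list[str]
) -> tuple[list[str], CoxFit | None]:
    """Bidirectional stepwise Cox selection minimizing AIC.

    Starts from the empty model (AIC = −2·null log-likelihood); at each
    step the single add or drop with the largest AIC improvement is
    taken, ties broken by feature name. Returns the selected features
    (possibly empty) and the final fit.
    """
    if len(features) < 2:
        raise ValueError("need at least two candidate features")
    features = list(dict.fromkeys(features))
    selected: list[str] = []
    current_aic = -2.0 * null_loglik(records)
    current_fit: CoxFit | None = None

    def try_fit(names: list[str]) -> CoxFit | None:
        try:
            fit = cox_fit(records, names)
        except ValueError:
            return None
        return fit if fit.converged else None

    while True:
        moves: list[tuple[float, str, str]] = []
        for f in sorted(set(features) - set(selected)):
            fit = try_fit(selected + [f])
            if fit is not None:
                moves.append((fit.aic, "add", f))
        for f in sorted(selected):
            names = [g for g in selected if g != f]
            if names:
                fit = try_fit(names)
                aic = fit.aic if fit is not None else np.inf
            else:
                aic = -2.0 * null_loglik(records)
            moves.append((aic, "drop", f))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[2]))
        best_aic, action, feat = moves[0]
        if best_aic >= current_aic - 1e-9:
            break
        if action == "add":
            selected.append(feat)
        else:
            selected.remove(feat)
        current_aic = best_aic
        current_fit = try_fit(selected) if selected else None
    return sorted(selected), current_fit


def compute_tmb(mutation_count: pd.Series, megabases: float = 40.0) -> pd.Series:
    """Tumor mutational burden: mutations per megabase of coding sequence."""
    if (mutation_count < 0).any():
        raise ValueError("negative mutation count")
    return (mutation_count / megabases).rename("tmb")


def hypergeometric_enrichment(labels_a: pd.Series, labels_b: pd.Series) -> pd.DataFrame:
    """Upper-tail hypergeometric overlap p per (class of A, class of B).

    For clusters vs an external classification: with N samples, K in the
    A-class, n in the B-class and k shared, p = P(X >= k) for
    X ~ Hypergeom(N, K, n).
    """
    shared = labels_a.index.intersection(labels_b.index)
    if len(shared) == 0:
        raise ValueError("no shared samples")
    a = labels_a.loc[shared]
    b = labels_b.loc[shared]
    n_total = len(shared)
    out = pd.DataFrame(
        index=sorted(a.dropna().unique()), columns=sorted(b.dropna().unique()), dtype=float
    )
    for ca in out.index:
        in_a = a == ca
        for cb in out.columns:
            in_b = b == cb
            k = int((in_a & in_b).sum())
            out.loc[ca, cb] = float(stats.hypergeom.sf(k - 1, n_total, int(in_a.sum()), int(in_b.sum())))
    return out
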