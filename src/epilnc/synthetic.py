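"""Synthetic paired methylome/transcriptome cohort with planted ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes in a tumor cohort profiled on a 450K-style methylation array and
by RNA-seq:

* two latent immune subtypes ("Hot" / "Cold");
* a planted set of epigenetically regulated (ER) lncRNAs, hypomethylated
  in the Hot subtype with expression negatively coupled to promoter
  methylation;
* a latent per-sample immune activity that drives immune-cell
  infiltration fractions, immune pathway/signature gene expression and a
  subset of "immune" ER lncRNAs;
* exponential survival with a configurable Hot-vs-Cold hazard ratio and
  independent uniform censoring.

Everything is a pure function of ``(CohortConfig, seed)``; two calls with
the same config produce bitwise-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import io_annotation as ioa

__all__ = ["CohortConfig", "GroundTruth", "Cohort", "generate_cohort", "ground_truth", "write_cohort"]

#: immune cell types reported by TIMER-style deconvolution
CELL_TYPES = ("B_cell", "CD4_T", "CD8_T", "Neutrophil", "Macrophage", "Dendritic")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``delta_beta_effect`` is the Hot-vs-Cold promoter-methylation
    difference planted for ER lncRNAs (beta-value units);
    ``meth_expr_rho`` the target Pearson correlation between an ER
    lncRNA's promoter beta and its log2 expression (0 disables the
    coupling, as does ``delta_beta_effect = 0`` for the methylation
    shift); ``infiltration_shift`` the Hot-vs-Cold difference in
    infiltration fractions; ``hazard_ratio_hot`` the survival hazard of
    Hot relative to Cold.
    """

    n_samples: int = 300
    n_lncrna: int = 1000
    n_pcg: int = 1200
    n_probes_per_gene: tuple[int, int] = (2, 8)
    frac_er: float = 0.05
    delta_beta_effect: float = 0.3
    meth_expr_rho: float = -0.6
    subtype_proportions: tuple[float, float] = (0.5, 0.5)
    infiltration_shift: float = 0.3
    hazard_ratio_hot: float = 2.0
    censoring_fraction: float = 0.3
    n_immune_lncrna: int = 20
    beta_precision: float = 60.0
    expr_slope: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        if not 0.0 <= self.frac_er <= 1.0:
            raise ValueError("frac_er must be in [0, 1]")
        if not 0.0 <= self.delta_beta_effect < 1.0:
            raise ValueError("delta_beta_effect must be in [0, 1)")
        if not -1.0 < self.meth_expr_rho <= 0.0:
            raise ValueError("meth_expr_rho must be in (-1, 0]")
        if self.frac_er * self.n_lncrna < 1:
            raise ValueError("infeasible config: frac_er * n_lncrna < 1")
        if self.n_samples < 10:
            raise ValueError("need at least 10 samples")


@dataclass
class GroundTruth:
    """Planted labels used by recovery-based tests."""

    subtype_labels: pd.Series  # sample -> "Hot"/"Cold"
    er_lncrnas: set[str]
    immune_lncrnas: set[str]
    pathway_links: list[tuple[str, str]]


@dataclass
class Cohort:
    """All pipeline inputs plus the ground truth that generated them."""

    config: CohortConfig
    probes: pd.DataFrame
    genes: pd.DataFrame
    meth: pd.DataFrame  # probe-level betas
    expr: pd.DataFrame  # log2 expression
    infiltration: pd.DataFrame  # samples x cell types
    clinical: pd.DataFrame
    gene_sets: dict[str, dict[str, set[str]]]
    response: pd.Series  # sample -> "responder"/"non_responder"
    truth: GroundTruth
    gene_beta: pd.DataFrame = field(repr=False, default=None)  # latent gene-level betas


def _beta_draw(rng, mean, precision, size):
    mean = np.clip(mean, 0.02, 0.98)
    a = mean * precision
    b = (1.0 - mean) * precision
    return rng.beta(a, b, size=size)


def _censoring_cmax(rates: np.ndarray, target: float) -> float:
    """Upper bound of U(0, cmax) censoring yielding the target censored fraction.

    For T ~ Exp(rate) and C ~ U(0, cmax), P(C < T) averaged over the
    per-sample rates is solved for cmax by bisection.
    """

    def frac(cmax):
        x = rates * cmax
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-6, 1e6
    if frac(hi) > target:  # even huge follow-up censors more than asked
        return hi
    return brentq(lambda c: frac(c) - target, lo, hi, xtol=1e-6)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic cohort; see the module docstring."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    n_hot = int(round(cfg.subtype_proportions[0] * cfg.n_samples))
    subtype = np.array(["Cold"] * cfg.n_samples, dtype=object)
    subtype[rng.choice(cfg.n_samples, size=n_hot, replace=False)] = "Hot"
    hot = (subtype == "Hot").astype(float)
    labels = pd.Series(subtype, index=samples, name="subtype")

    lnc_ids = [f"LNC{i:04d}" for i in range(cfg.n_lncrna)]
    pcg_ids = [f"PCG{i:04d}" for i in range(cfg.n_pcg - 2)] + ["GZMA", "PRF1"]
    gene_ids = lnc_ids + pcg_ids

    # gene annotation: genes tiled 10 kb apart so promoter windows are disjoint
    chroms, tss = [], []
    per_chrom = int(np.ceil(len(gene_ids) / 22))
    for i in range(len(gene_ids)):
        chroms.append(f"chr{i // per_chrom + 1}")
        tss.append(50_000 + 10_000 * (i % per_chrom))
    genes = pd.DataFrame(
        {
            "biotype": ["lncRNA"] * len(lnc_ids) + ["PCG"] * len(pcg_ids),
            "chrom": chroms,
            "strand": rng.choice(["+", "-"], size=len(gene_ids)),
            "tss": tss,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # planted gene programs ------------------------------------------------
    k_er = int(round(cfg.frac_er * cfg.n_lncrna))
    er_ids = list(rng.choice(lnc_ids, size=k_er, replace=False))
    immune_lncs = er_ids[: min(cfg.n_immune_lncrna, k_er)]

    pcg_pool = [g for g in pcg_ids if g not in ("GZMA", "PRF1")]
    rng.shuffle(pcg_pool)
    cursor = 0

    def take(n):
        nonlocal cursor
        out = pcg_pool[cursor : cursor + n]
        cursor += n
        return out

    # gene-set sizes scale down with the PCG pool so small cohorts stay valid
    pool = len(pcg_pool)
    scale = min(1.0, pool / 455.0)
    pw_size = max(5, int(25 * scale))
    sig_size = max(5, int(15 * scale))
    small_size = max(4, int(10 * scale))
    est_size = max(8, int(30 * scale))
    if 12 * pw_size + 5 * sig_size + 2 * small_size + 2 * est_size > pool:
        raise ValueError("n_pcg too small to carve out the immune gene sets")
    pathway_names = [f"PW_IMMUNE_{i}" for i in range(6)] + [f"PW_NULL_{i}" for i in range(6)]
    pathways = {name: set(take(pw_size)) for name in pathway_names}
    immune_pathways = pathway_names[:6]
    signatures = {
        name: set(take(sig_size))
        for name in ("IFN_gamma_response", "TIL", "HLA", "Checkpoint", "Macrophage_monocyte")
    }
    mhc1 = set(take(small_size))
    markers = set(take(small_size)) | {"GZMA", "PRF1"}
    stromal_set = set(take(est_size))
    immune_est_set = set(take(est_size))
    act_coupled = (
        set().union(*(pathways[p] for p in immune_pathways))
        | set().union(*signatures.values())
        | mhc1
        | markers
        | immune_est_set
    )

    # latent immune activity: elevated in Hot, scaled by infiltration_shift
    act = hot + rng.normal(0.0, 0.35, cfg.n_samples)
    stromal_act = rng.normal(0.0, 1.0, cfg.n_samples)

    # gene-level promoter betas -------------------------------------------
    meth_shifted = set(er_ids) | set(
        rng.choice(sorted(act_coupled), size=min(40, len(act_coupled)), replace=False)
    )
    mu_base = rng.uniform(0.15, 0.85, size=len(gene_ids))
    gene_beta = np.empty((len(gene_ids), cfg.n_samples))
    for i, g in enumerate(gene_ids):
        if g in meth_shifted and cfg.delta_beta_effect > 0:
            mu_cold = rng.uniform(0.5, 0.75)
            mu = np.where(hot == 1.0, mu_cold - cfg.delta_beta_effect, mu_cold)
        else:
            mu = np.full(cfg.n_samples, mu_base[i])
        gene_beta[i] = _beta_draw(rng, mu, cfg.beta_precision, cfg.n_samples)
    gene_beta_df = pd.DataFrame(gene_beta, index=gene_ids, columns=samples)

    # probe-level betas: jitter around the gene value inside the promoter
    lo, hi = cfg.n_probes_per_gene
    probe_rows, probe_beta_rows = [], []
    for i, g in enumerate(gene_ids):
        n_pr = int(rng.integers(lo, hi + 1))
        offsets = rng.choice(np.arange(-2000, 2000), size=n_pr, replace=False)
        for j, off in enumerate(sorted(offsets)):
            probe_rows.append(
                (f"cg_{g}_{j}", genes.loc[g, "chrom"], int(genes.loc[g, "tss"]) + int(off))
            )
            probe_beta_rows.append(
                np.clip(gene_beta[i] + rng.normal(0.0, 0.03, cfg.n_samples), 0.0, 1.0)
            )
    probes = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "pos"]
    ).set_index("probe_id")
    meth = pd.DataFrame(np.vstack(probe_beta_rows), index=probes.index, columns=samples)

    # expression ----------------------------------------------------------
    expr = np.empty((len(gene_ids), cfg.n_samples))
    base_expr = rng.uniform(1.0, 6.0, size=len(gene_ids))
    rho = cfg.meth_expr_rho
    for i, g in enumerate(gene_ids):
        if g in er_ids and rho < 0:
            signal = cfg.expr_slope * (1.0 - gene_beta[i])
            if g in immune_lncs:
                signal = signal + 1.0 * act
            b = gene_beta[i]
            cov_sb = float(np.cov(signal, b)[0, 1])
            var_s = float(np.var(signal, ddof=1))
            sd_b = float(np.std(b, ddof=1))
            # noise sd solving corr(signal + eps, beta) = rho; clamp when the
            # composed signal cannot be decorrelated down to the target
            var_eps = (cov_sb / (rho * sd_b)) ** 2 - var_s
            sd_eps = np.sqrt(max(var_eps, 1e-4))
            expr[i] = 2.0 + signal + rng.normal(0.0, sd_eps, cfg.n_samples)
        elif g in act_coupled:
            d = rng.uniform(0.8, 1.2)
            expr[i] = base_expr[i] + d * cfg.infiltration_shift * 4.0 * act + rng.normal(
                0.0, 0.8, cfg.n_samples
            )
        elif g in stromal_set:
            expr[i] = base_expr[i] + 0.8 * stromal_act + rng.normal(0.0, 0.8, cfg.n_samples)
        else:
            expr[i] = base_expr[i] + rng.normal(0.0, 1.0, cfg.n_samples)
    expr = np.clip(expr, 0.0, None)
    expr_df = pd.DataFrame(expr, index=gene_ids, columns=samples)

    # infiltration ---------------------------------------------------------
    base_frac = dict(zip(CELL_TYPES, (0.10, 0.15, 0.08, 0.05, 0.12, 0.06)))
    weights = dict(zip(CELL_TYPES, (1.0, 0.6, 1.0, 0.8, 0.9, 0.7)))
    infil = {
        ct: np.clip(
            base_frac[ct] + weights[ct] * cfg.infiltration_shift * act
            + rng.normal(0.0, 0.02, cfg.n_samples),
            0.0,
            None,
        )
        for ct in CELL_TYPES
    }
    infiltration = pd.DataFrame(infil, index=samples)

    # clinical + survival --------------------------------------------------
    age = np.clip(np.round(rng.normal(55.0, 12.0, cfg.n_samples)), 20, 90)
    gender = rng.choice(["male", "female"], size=cfg.n_samples)
    grade = rng.choice(["II", "III", "IV"], size=cfg.n_samples, p=(0.3, 0.4, 0.3))
    base_rate = np.log(2.0) / 24.0  # median Cold survival 24 months
    rate = base_rate * np.power(cfg.hazard_ratio_hot, hot)
    t_event = rng.exponential(1.0 / rate)
    cmax = _censoring_cmax(rate, cfg.censoring_fraction)
    t_cens = rng.uniform(0.0, cmax, cfg.n_samples)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    mutations = rng.poisson(60.0 * (1.0 + 0.8 * hot))
    clinical = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "age": age,
            "gender": gender,
            "grade": grade,
            "mutation_count": mutations,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    # immunotherapy response: low immune activity responds worse; planted so
    # that immune lncRNA expression is decreased in responders
    p_resp = 1.0 / (1.0 + np.exp(2.0 * (act - 0.4)))
    response = pd.Series(
        np.where(rng.uniform(size=cfg.n_samples) < p_resp, "responder", "non_responder"),
        index=samples,
        name="response",
    )

    gene_sets = {
        "pathways": pathways,
        "signatures": signatures,
        "mhc1": {"MHC_I": mhc1},
        "markers": {"EVASION_MARKERS": markers},
        "estimate": {"STROMAL": stromal_set, "IMMUNE": immune_est_set},
    }
    truth = GroundTruth(
        subtype_labels=labels,
        er_lncrnas=set(er_ids),
        immune_lncrnas=set(immune_lncs),
        pathway_links=[(l, p) for l in immune_lncs for p in immune_pathways],
    )
    return Cohort(
        config=cfg,
        probes=probes,
        genes=genes,
        meth=meth,
        expr=expr_df,
        infiltration=infiltration,
        clinical=clinical,
        gene_sets=gene_sets,
        response=response,
        truth=truth,
        gene_beta=gene_beta_df,
    )


def ground_truth(cohort: Cohort) -> GroundTruth:
    """Planted labels of a generated cohort (for recovery-based checks)."""
    return cohort.truth


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write every pipeline input plus a ground-truth JSON under *outdir*."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.probes.to_csv(out / "probes.tsv", sep="\t")
    cohort.genes.to_csv(out / "genes.tsv", sep="\t")
    ioa.write_matrix(cohort.meth, out / "methylation.tsv")
    ioa.write_matrix(cohort.expr, out / "expression.tsv")
    ioa.write_matrix(cohort.infiltration, out / "infiltration.tsv")
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t")
    cohort.response.to_frame().to_csv(out / "response.tsv", sep="\t")
    for name, sets in cohort.gene_sets.items():
        ioa.write_gmt(sets, out / f"{name}.gmt")
    truth = cohort.truth
    payload = {
        "subtype_labels": truth.subtype_labels.to_dict(),
        "er_lncrnas": sorted(truth.er_lncrnas),
        "immune_lncrnas": sorted(truth.immune_lncrnas),
        "pathway_links": [list(t) for t in truth.pathway_links],
        "config": asdict(cohort.config),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
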