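"""End-to-end orchestration of the lncRNA-methylation immune subtyping analysis.

Stage order: promoter methylation summarization -> consensus subtype
discovery -> ER lncRNA detection -> immune scoring and immune-lncRNA
prioritization -> survival statistics -> evasion association. A single
master seed is fanned out to per-stage child seeds by stable hashing of
the stage name, so adding a stage never perturbs earlier ones. The run
is a pure function of (inputs, config, seed): repeated runs produce a
byte-identical ``report.json``.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import er as er_mod
from . import evasion as evasion_mod
from . import immune as immune_mod
from . import io_annotation as ioa
from . import subtype as subtype_mod
from . import survival as survival_mod

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "stage_seed"]

log = logging.getLogger("epilnc")

#: filenames written by synthetic.write_cohort and read back here
_INPUT_FILES = {
    "meth": "methylation.tsv",
    "probes": "probes.tsv",
    "genes": "genes.tsv",
    "expr": "expression.tsv",
    "infiltration": "infiltration.tsv",
    "clinical": "clinical.tsv",
    "response": "response.tsv",
    "pathways": "pathways.gmt",
    "signatures": "signatures.gmt",
    "mhc1": "mhc1.gmt",
    "markers": "markers.gmt",
    "estimate": "estimate.gmt",
}


class PipelineError(RuntimeError):
    """Raised when a stage fails; the message names the stage."""


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str | None = None
    half_window: int = 2000
    variance_fraction: float = 0.05
    k_min: int = 2
    k_max: int = 6
    n_iter: int = 1000
    subsample_frac: float = 0.8
    min_cluster_size: int = 5
    delta_thresh: float = 0.2
    alpha: float = 0.05
    logfc_thresh: float = 0.75
    min_cells_passed: int = 4
    n_perm: int = 200
    max_assoc_lncrnas: int = 25
    seed: int = 0


def stage_seed(master_seed: int, stage: str) -> int:
    """Child seed for a stage: stable hash of (master seed, stage name)."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


def _load_inputs(cfg: PipelineConfig) -> dict:
    d = Path(cfg.input_dir)
    inputs = {}
    for key, fname in _INPUT_FILES.items():
        path = d / fname
        if not path.exists():
            if key == "response":
                inputs[key] = None
                continue
            raise FileNotFoundError(f"missing input file {path}")
        if fname.endswith(".gmt"):
            inputs[key] = ioa.read_gmt(path)
        else:
            inputs[key] = ioa.read_matrix(path)
    if inputs["response"] is not None:
        inputs["response"] = inputs["response"].iloc[:, 0]
    ioa.validate_beta_matrix(inputs["meth"])
    return inputs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write stage tables and report.json if output_dir set."""
    cfg = config
    outdir = Path(cfg.output_dir) if cfg.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("io_annotation")
        inputs = _load_inputs(cfg)
        mapping = ioa.map_probes_to_promoters(inputs["probes"], inputs["genes"], cfg.half_window)
        prom = ioa.promoter_beta(inputs["meth"], mapping)
        lnc_ids = [
            g for g in prom.index if inputs["genes"].loc[g, "biotype"] == "lncRNA"
        ]
        prom_lnc = prom.loc[lnc_ids]
    except Exception as exc:
        raise PipelineError(f"stage io_annotation failed: {exc}") from exc

    try:
        stage("subtype_discovery")
        features = subtype_mod.select_variable_features(prom_lnc, cfg.variance_fraction)
        sseed = stage_seed(cfg.seed, "subtype_discovery")
        results = [
            subtype_mod.consensus_cluster(
                prom_lnc.loc[features], k, cfg.n_iter, cfg.subsample_frac, sseed
            )
            for k in range(cfg.k_min, cfg.k_max + 1)
        ]
        chosen = subtype_mod.select_k(results)
        labels = subtype_mod.filter_small_clusters(chosen.labels, cfg.min_cluster_size)
        assigned = labels[labels != subtype_mod.UNASSIGNED]
        # cluster 1 = immune-hot (largest mean infiltration across cell types)
        infil_mean = inputs["infiltration"].mean(axis=1)
        cluster_heat = {
            c: float(infil_mean.loc[assigned.index[assigned == c]].mean())
            for c in sorted(assigned.unique())
        }
        hot_first = sorted(cluster_heat, key=lambda c: -cluster_heat[c])
        relabel = {c: i + 1 for i, c in enumerate(hot_first)}
        assigned = assigned.map(relabel)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage subtype_discovery failed: {exc}") from exc

    try:
        stage("er_lncrna")
        two_cluster = assigned[assigned.isin([1, 2])]
        dm = er_mod.differential_methylation(prom_lnc, two_cluster)
        er_table = er_mod.classify_er(
            dm, prom_lnc, inputs["expr"], cfg.delta_thresh, cfg.alpha
        )
        er_ids = sorted(er_table.index[er_table["is_er"]])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage er_lncrna failed: {exc}") from exc

    try:
        stage("immune_scoring")
        expr = inputs["expr"]
        sig_scores = immune_mod.signature_scores(expr, inputs["signatures"])
        cyt = immune_mod.cyt_score(expr)
        mhc = immune_mod.mhc_score(expr, next(iter(inputs["mhc1"].values())))
        est = immune_mod.estimate_like(
            expr, inputs["estimate"]["STROMAL"], inputs["estimate"]["IMMUNE"]
        )
        purity = immune_mod.purity_from_estimate(est["combined"])
        pcg_ids = [g for g in expr.index if inputs["genes"].loc[g, "biotype"] == "PCG"]
        de = immune_mod.differential_expression(
            expr.loc[pcg_ids], two_cluster, cfg.logfc_thresh, cfg.alpha
        )
        pairs, verdicts = immune_mod.infiltration_correlation(
            expr, prom_lnc, inputs["infiltration"], er_ids, cfg.alpha
        )
        immune_lncs = sorted(
            verdicts.index[verdicts["n_cells_passed"] >= cfg.min_cells_passed]
        )
        iseed = stage_seed(cfg.seed, "immune_scoring")
        assoc_tables = []
        for lnc in immune_lncs[: cfg.max_assoc_lncrnas]:
            assoc_tables.append(
                immune_mod.lncrna_pathway_association(
                    expr,
                    lnc,
                    inputs["pathways"],
                    purity,
                    pcg_ids=pcg_ids,
                    n_perm=cfg.n_perm,
                    alpha=cfg.alpha,
                    seed=stage_seed(iseed, lnc),
                )
            )
        assoc = (
            pd.concat(assoc_tables, ignore_index=True)
            if assoc_tables
            else pd.DataFrame(columns=["lncrna", "pathway", "es", "nes", "p_perm", "fdr"])
        )
        n_hits = int(((assoc["fdr"] < cfg.alpha) & (assoc["es"] > 0)).sum()) if len(assoc) else 0
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage immune_scoring failed: {exc}") from exc

    try:
        stage("survival_stats")
        clin = inputs["clinical"].loc[two_cluster.index].copy()
        clin["subtype"] = two_cluster.astype(str)
        chi2, logrank_p = survival_mod.logrank_test(clin, clin["subtype"])
        ladder = survival_mod.lr_ladder(clin, ["grade", "subtype"])
        selected, _ = survival_mod.stepwise_cox(clin, ["age", "grade", "subtype", "gender"])
        tmb = survival_mod.compute_tmb(clin["mutation_count"])
        tmb_by_cluster = {
            str(c): float(tmb.loc[two_cluster.index[two_cluster == c]].mean())
            for c in sorted(two_cluster.unique())
        }
        enrich = survival_mod.hypergeometric_enrichment(two_cluster.astype(str), clin["grade"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage survival_stats failed: {exc}") from exc

    try:
        stage("evasion")
        marker_genes = sorted(next(iter(inputs["markers"].values())))
        marker_expr = expr.loc[expr.index.intersection(marker_genes)]
        ev_lncs = immune_lncs if immune_lncs else er_ids[:10]
        markers_tab = (
            evasion_mod.marker_correlation(expr.loc[ev_lncs], marker_expr)
            if ev_lncs
            else pd.DataFrame()
        )
        if inputs["response"] is not None and ev_lncs:
            resp_tab = evasion_mod.response_association(expr.loc[ev_lncs], inputs["response"])
        else:
            resp_tab = pd.DataFrame()
        prog = (
            evasion_mod.prognosis_comparison(prom_lnc, expr, clin, ev_lncs)
            if ev_lncs
            else pd.DataFrame()
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage evasion failed: {exc}") from exc

    from . import __version__

    report = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v for k, v in sorted(asdict(cfg).items()) if k not in ("input_dir", "output_dir")
        },
        "engine_notes": {
            "differential_expression": "wilcoxon_logfc",
            "cox_ties": "efron",
        },
        "counts": {
            "n_samples": int(inputs["meth"].shape[1]),
            "n_genes_with_promoter": int(prom.shape[0]),
            "n_lncrna_promoters": int(prom_lnc.shape[0]),
            "n_features_selected": len(features),
            "chosen_k": int(chosen.chosen_k),
            "cluster_sizes": {
                str(c): int((assigned == c).sum()) for c in sorted(assigned.unique())
            },
            "n_er_lncrnas": len(er_ids),
            "n_er_hypo_in_hot": int(
                (er_table.loc[er_ids, "direction"] == "hypo_up").sum()
            ),
            "n_immune_lncrnas": len(immune_lncs),
            "n_pathway_hits": n_hits,
            "n_de_flagged": int(de["flag"].sum()),
        },
        "per_k_pac": {str(k): v["pac"] for k, v in chosen.per_k_stats.items()},
        "survival": {
            "logrank_chi2": chi2,
            "logrank_p": logrank_p,
            "lr_ladder": {f: float(ladder.loc[f, "lr"]) for f in ladder.index},
            "stepwise_selected": selected,
            "tmb_by_cluster": tmb_by_cluster,
        },
    }

    if outdir:
        ioa.write_matrix(prom, outdir / "promoter_beta.tsv")
        assigned.rename("cluster").to_frame().to_csv(outdir / "subtypes.tsv", sep="\t")
        er_table.to_csv(outdir / "er_records.tsv", sep="\t")
        sig_scores.to_csv(outdir / "signature_scores.tsv", sep="\t")
        pd.DataFrame({"CYT": cyt, "MHC": mhc}).join(est).to_csv(
            outdir / "immunoactivity_scores.tsv", sep="\t"
        )
        de.to_csv(outdir / "differential_expression.tsv", sep="\t")
        pairs.to_csv(outdir / "infiltration_pairs.tsv", sep="\t", index=False)
        assoc.to_csv(outdir / "pathway_associations.tsv", sep="\t", index=False)
        ladder.to_csv(outdir / "lr_ladder.tsv", sep="\t")
        enrich.to_csv(outdir / "grade_enrichment.tsv", sep="\t")
        if len(markers_tab):
            markers_tab.to_csv(outdir / "marker_correlations.tsv", sep="\t", index=False)
        if len(resp_tab):
            resp_tab.to_csv(outdir / "response_association.tsv", sep="\t")
        if len(prog):
            prog.to_csv(outdir / "prognosis_comparison.tsv", sep="\t")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return report
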