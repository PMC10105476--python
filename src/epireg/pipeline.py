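"""End-to-end orchestration: preprocessing, survival statistics, and the
full screen -> aberrance -> cluster -> signatures -> NTP -> ssGSEA ->
drug-screen -> survival pipeline with a JSON run report.

The pipeline consumes either TSV inputs on disk or a synthetic cohort
generated in place from a :class:`~epireg.simulate.SimConfig`; every
intermediate artifact is written under the output directory in the
package's plain-text formats, and a single integer seed propagates to
every stochastic stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from . import io
from .aberrance import AberranceConfig, aberrance_profile, \
    coregulation_correlation
from .cluster import ClusterConfig, select_k
from .drugs import DrugScreenConfig, filter_and_impute, \
    subtype_specific_drugs
from .immune import SsgseaParams, ssgsea_scores
from .screen import ScreenConfig, collect_regulated_genes, overlap_genes, \
    pair_cpg_genes, pair_mirna_genes, region_frequency, score_pairs, \
    write_pair_table
from .simulate import SimConfig, simulate_cohort, simulate_drug_panel, \
    write_cohort
from .subtypes import extract_signatures, ntp_classify

log = logging.getLogger("epireg")


def preprocess_expression(raw: pd.DataFrame,
                          max_missing_frac: float = 0.20,
                          transform: str = "log2p1") -> pd.DataFrame:
    """Drop features with a missing fraction strictly above the cutoff,
    impute the remaining gaps with the feature median, and apply the
    transform (``log2p1`` = log2(x+1), or ``none``)."""
    vals = raw.to_numpy(float)
    if np.nanmin(vals) < 0:
        raise ValueError("expression values must be non-negative")
    keep = raw.isna().mean(axis=1) <= max_missing_frac
    out = raw.loc[keep].copy()
    med = out.median(axis=1)
    out = out.apply(lambda row: row.fillna(med[row.name]), axis=1)
    if transform == "log2p1":
        out = np.log2(out + 1.0)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    return out


def km_logrank(survival: pd.DataFrame, labels: pd.Series):
    """Kaplan-Meier curves per group plus the k-group log-rank test.

    Returns ``(curves, statistic, p)`` where curves maps group -> the
    product-limit survival function (DataFrame indexed by time)."""
    surv = survival.set_index("sample")
    shared = surv.index.intersection(labels.index)
    if len(shared) == 0:
        raise ValueError("survival table and labels share no samples")
    surv = surv.loc[shared]
    lab = labels.loc[shared]
    groups = sorted(lab.unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups for the log-rank test")
    events_per_group = surv.groupby(lab)["event"].sum()
    if (events_per_group == 0).any():
        warnings.warn("group(s) with zero events: "
                      f"{events_per_group[events_per_group == 0].index.tolist()}; "
                      "log-rank test may be unstable")

    curves = {}
    for g in groups:
        kmf = KaplanMeierFitter()
        sub = surv[lab == g]
        kmf.fit(sub["time"], event_observed=sub["event"], label=str(g))
        curves[g] = kmf.survival_function_
    res = multivariate_logrank_test(surv["time"], lab, surv["event"])
    return curves, float(res.test_statistic), float(res.p_value)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs: input paths (or a synthetic
    cohort spec), per-stage configs, stage toggles, one seed, one outdir."""

    outdir: str = "epireg_run"
    seed: int = 0
    simulate: SimConfig | None = None
    paths: dict = field(default_factory=dict)
    stages: dict = field(default_factory=lambda: {
        "screen": True, "aberrance": True, "cluster": True,
        "signatures": True, "ntp": True, "ssgsea": True,
        "drugs": True, "survival": True})
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    aberrance: AberranceConfig = field(default_factory=AberranceConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    drugs: DrugScreenConfig = field(default_factory=DrugScreenConfig)
    ssgsea: SsgseaParams = field(default_factory=SsgseaParams)
    signature_top_n: int = 500
    signature_fdr_max: float = 0.05
    ntp_n_perm: int = 1000
    preprocess: bool = False
    max_missing_frac: float = 0.20

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "simulate" in kwargs and kwargs["simulate"] is not None:
            kwargs["simulate"] = SimConfig(**kwargs["simulate"])
        for key, klass in (("screen", ScreenConfig),
                           ("aberrance", AberranceConfig),
                           ("cluster", ClusterConfig),
                           ("drugs", DrugScreenConfig),
                           ("ssgsea", SsgseaParams)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = kwargs[key]
                if key in ("screen",) and "promoter_classes" in sub \
                        and sub["promoter_classes"] is not None:
                    sub["promoter_classes"] = tuple(sub["promoter_classes"])
                if key == "cluster" and "k_range" in sub:
                    sub["k_range"] = tuple(sub["k_range"])
                kwargs[key] = klass(**sub)
        return cls(**kwargs)


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.simulate is not None:
        sim = cfg.simulate
        sim.seed = cfg.seed
        mrna, mirna, meth, annot, lists, survival, truth = \
            simulate_cohort(sim)
        write_cohort(outdir / "inputs", mrna, mirna, meth, annot, lists,
                     survival, truth)
        auc, cellline_expr, _true_drugs = simulate_drug_panel(
            sim, truth.labels)
        auc.to_csv(outdir / "inputs" / "auc.tsv", sep="\t",
                   index_label="sample")
        return dict(mrna=mrna, mirna=mirna, meth=meth, annot=annot,
                    lists=lists, survival=survival, auc=auc,
                    cellline_expr=cellline_expr)
    p = cfg.paths
    data = dict(
        mrna=io.read_omics_matrix(p["mrna"]),
        mirna=io.read_omics_matrix(p["mirna"]),
        meth=io.read_omics_matrix(p["meth"]),
        annot=io.read_cpg_annotation(p["cpg_annot"]),
        lists=[io.read_target_list(q) for q in p["target_lists"]],
        survival=io.read_survival_table(p["survival"]) if "survival" in p
        else None,
        auc=pd.read_csv(p["auc"], sep="\t", index_col=0) if "auc" in p
        else None,
        cellline_expr=io.read_omics_matrix(p["cellline_expr"])
        if "cellline_expr" in p else None,
    )
    if "gene_sets" in p:
        data["gene_sets"] = io.read_gmt(p["gene_sets"])
    return data


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and return the run
    report (also written to ``<outdir>/report.json``)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}
    data = _load_inputs(cfg, outdir)
    mrna = data["mrna"]
    if cfg.preprocess:
        mrna = preprocess_expression(mrna, cfg.max_missing_frac)

    met_genes = mir_genes = None
    labels = None
    sig = None

    def require(stage: str, needed, value):
        if value is None:
            raise RuntimeError(
                f"stage {stage!r} requires output of disabled stage "
                f"{needed!r}; enable it or supply the artifact")
        return value

    if cfg.stages.get("screen", True):
        log.info("stage screen")
        cand_cpg = pair_cpg_genes(data["meth"], mrna, data["annot"],
                                  cfg.screen)
        scored_cpg = score_pairs(cand_cpg, data["meth"], mrna, cfg.screen)
        cand_mir = pair_mirna_genes(data["lists"], data["mirna"], mrna)
        scored_mir = score_pairs(cand_mir, data["mirna"], mrna, cfg.screen)
        met_genes, met_best = collect_regulated_genes(scored_cpg)
        mir_genes, mir_best = collect_regulated_genes(scored_mir)
        both, counts = overlap_genes(met_genes, mir_genes)
        freq = region_frequency(scored_cpg, data["annot"])
        write_pair_table(scored_cpg, outdir / "pairs_cpg.tsv")
        write_pair_table(scored_mir, outdir / "pairs_mirna.tsv")
        io.write_gene_list(sorted(met_genes), outdir / "metcor_genes.txt")
        io.write_gene_list(sorted(mir_genes), outdir / "mircor_genes.txt")
        freq.to_csv(outdir / "region_frequency.tsv", sep="\t", index=False)
        report["stages"]["screen"] = {
            "candidate_cpg_pairs": int(len(cand_cpg)),
            "candidate_mirna_pairs": int(len(cand_mir)),
            "significant_cpg_pairs": int(scored_cpg["significant"].sum()),
            "significant_mirna_pairs": int(scored_mir["significant"].sum()),
            "metcor_genes": len(met_genes),
            "mircor_genes": len(mir_genes),
            "overlap": counts,
        }

    if cfg.stages.get("aberrance", True):
        log.info("stage aberrance")
        mg = require("aberrance", "screen", met_genes)
        rg = require("aberrance", "screen", mir_genes)
        p_met = aberrance_profile(mrna, mg, "METcor", cfg.aberrance)
        p_mir = aberrance_profile(mrna, rg, "MIRcor", cfg.aberrance)
        r, pval, cm, _pm = coregulation_correlation(p_met, p_mir)
        pd.concat([p_met, p_mir]).to_csv(outdir / "aberrance.tsv",
                                         sep="\t", index=False)
        cm.to_csv(outdir / "aberrance_corr_matrix.tsv", sep="\t")
        report["stages"]["aberrance"] = {"cor": r, "p": pval}

    if cfg.stages.get("cluster", True):
        log.info("stage cluster")
        mg = require("cluster", "screen", met_genes)
        rg = require("cluster", "screen", mir_genes)
        ccfg = cfg.cluster
        ccfg.seed = cfg.seed
        blocks = [("METcor", mrna.loc[sorted(mg & set(mrna.index))]),
                  ("MIRcor", mrna.loc[sorted(rg & set(mrna.index))])]
        model = select_k(blocks, ccfg)
        labels = model.labels
        labels.rename("subtype").to_frame().to_csv(
            outdir / "subtype_labels.tsv", sep="\t", index_label="sample")
        pd.DataFrame({"k": list(model.bic),
                      "bic": list(model.bic.values()),
                      "deviance_ratio":
                      [model.deviance_ratio[k] for k in model.bic]}) \
            .to_csv(outdir / "bic_trace.tsv", sep="\t", index=False)
        report["stages"]["cluster"] = {
            "chosen_k": model.k,
            "sizes": {int(s): int(c) for s, c in
                      labels.value_counts().sort_index().items()},
            "bic": model.bic, "converged": model.converged,
        }

    if cfg.stages.get("signatures", True):
        log.info("stage signatures")
        lab = require("signatures", "cluster", labels)
        sig = extract_signatures(mrna, lab, top_n=cfg.signature_top_n,
                                 fdr_max=cfg.signature_fdr_max)
        io.write_gmt({str(s): list(t["gene"])
                      for s, t in sig.tables.items()},
                     outdir / "signatures.gmt")
        pd.concat([t.assign(subtype=s) for s, t in sig.tables.items()]) \
            .to_csv(outdir / "signatures.tsv", sep="\t", index=False)
        report["stages"]["signatures"] = {
            "sizes": {int(s): int(len(t)) for s, t in sig.tables.items()}}

    if cfg.stages.get("ntp", True):
        log.info("stage ntp")
        s = require("ntp", "signatures", sig)
        lab = require("ntp", "cluster", labels)
        ntp = ntp_classify(mrna, s, n_perm=cfg.ntp_n_perm, seed=cfg.seed)
        ntp.to_csv(outdir / "ntp.tsv", sep="\t", index=False)
        agree = float((ntp.set_index("sample")["subtype"]
                       .reindex(lab.index) == lab).mean())
        report["stages"]["ntp"] = {"self_agreement": agree}

    if cfg.stages.get("ssgsea", True):
        log.info("stage ssgsea")
        sets = data.get("gene_sets")
        if sets is None:
            s = require("ssgsea", "signatures", sig)
            sets = {f"subtype_{k}": v[:50]
                    for k, v in s.gene_sets().items()}
        scores = ssgsea_scores(mrna, sets, cfg.ssgsea)
        scores.to_csv(outdir / "ssgsea.tsv", sep="\t",
                      index_label="sample")
        report["stages"]["ssgsea"] = {"n_sets": int(scores.shape[1])}

    if cfg.stages.get("drugs", True) and data.get("auc") is not None:
        log.info("stage drugs")
        lab = require("drugs", "cluster", labels)
        dcfg = cfg.drugs
        dcfg.seed = cfg.seed
        auc_complete = filter_and_impute(data["auc"], dcfg)
        res = subtype_specific_drugs(auc_complete, lab, dcfg)
        res.table.to_csv(outdir / "drug_screen.tsv", sep="\t", index=False)
        report["stages"]["drugs"] = {
            "drugs_retained": int(auc_complete.shape[1]),
            "assigned": {int(s): sorted(d)
                         for s, d in res.assignments.items()},
        }

    if cfg.stages.get("survival", True) and data.get("survival") is not None:
        log.info("stage survival")
        lab = require("survival", "cluster", labels)
        _curves, stat, p = km_logrank(data["survival"], lab)
        report["stages"]["survival"] = {"logrank_stat": stat, "p": p}

    io.write_json(report, outdir / "report.json")
    return report
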