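"""Synthetic multi-omics cohorts with planted ground truth.

The generator emulates the structure of a tumor cohort profiled on three
omics layers (mRNA log-expression, miRNA log-expression, promoter CpG
methylation betas) together with survival follow-up and a drug-response
panel:

* a configurable number of CpG-gene and miRNA-gene pairs are planted with
  an exact negative population Pearson correlation (``target_r``); all
  remaining pairs are independent;
* samples belong to one of ``n_subtypes`` molecular subtypes; each subtype
  carries a set of differentially expressed genes shifted by
  ``effect_size_delta`` within-gene standard deviations;
* survival times are exponential with a per-subtype hazard and independent
  exponential censoring;
* the drug panel plants subtype-specific compounds whose AUC is lower by
  ``drug_effect_log2`` (log2 scale) in the sensitive subtype, with random
  missingness.

Methylation is simulated on the logit (M-value-like) scale and squashed
through the inverse logit, so betas stay in (0,1) while the planted
correlation with expression is exact on the logit scale.  Regulatory
coupling is planted by drawing the regulator from the population-
standardized gene expression (which already includes subtype shifts), so
the pooled correlation equals ``target_r`` exactly even for genes that are
differentially expressed between subtypes.

All randomness derives from one integer seed through spawned child
generators, one per stage, so outputs are bit-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit  # noqa: F401  (logit used by callers)

from . import io

_ISLAND_P_TRUE = (0.60, 0.20, 0.10, 0.10)   # Island, Shore, Shelf, Opensea
_ISLAND_P_NULL = (0.30, 0.25, 0.15, 0.30)
_POSITION_P_TRUE = (0.40, 0.25, 0.10, 0.10, 0.10, 0.05)
_POSITION_P_NULL = (0.15, 0.15, 0.15, 0.15, 0.25, 0.15)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Counts and effect sizes default to the standard study conditions used
    throughout the test-suite: 200 samples, 300 planted pairs per
    regulatory layer at r = -0.5, four subtypes with unequal prevalence
    and a 1.5-SD expression shift on 150 genes each, exponential survival
    (hazards per month), and a 50-drug panel with three planted compounds
    per subtype at a 0.2 log2 AUC effect.
    """

    n_samples: int = 200
    n_genes: int = 2000
    n_cpgs: int = 1000
    n_mirnas: int = 300
    n_true_met_pairs: int = 300
    n_true_mir_pairs: int = 300
    target_r: float = -0.5
    n_subtypes: int = 4
    subtype_props: tuple = (0.30, 0.23, 0.15, 0.32)
    de_genes_per_subtype: int = 150
    effect_size_delta: float = 1.5
    hazard_per_subtype: tuple = (0.05, 0.08, 0.10, 0.15)
    censor_rate: float = 0.05
    n_drugs: int = 50
    planted_drugs_per_subtype: int = 3
    drug_effect_log2: float = 0.2
    auc_sd_log2: float = 0.05
    missing_frac: float = 0.10
    aberrance_coupling: float = 0.12
    decoys_per_list: int = 200
    decoy_overlap: int = 0
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_samples=self.n_samples, n_genes=self.n_genes,
                      n_cpgs=self.n_cpgs, n_mirnas=self.n_mirnas,
                      n_subtypes=self.n_subtypes, n_drugs=self.n_drugs)
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not (-1.0 < self.target_r <= 0.0):
            raise ValueError("target_r must lie in (-1, 0]")
        props = np.asarray(self.subtype_props, float)
        if len(props) != self.n_subtypes or not np.isclose(props.sum(), 1.0):
            raise ValueError("subtype_props must be a length-n_subtypes simplex")
        if len(self.hazard_per_subtype) != self.n_subtypes:
            raise ValueError("hazard_per_subtype must have one rate per subtype")
        if not (0.0 <= self.missing_frac < 1.0):
            raise ValueError("missing_frac must lie in [0, 1)")
        if self.n_true_met_pairs > self.n_cpgs:
            raise ValueError("more planted MET pairs than CpG probes")
        if self.n_true_mir_pairs > self.n_mirnas:
            raise ValueError("more planted MIR pairs than miRNAs")
        if self.n_true_met_pairs + self.n_true_mir_pairs > self.n_genes:
            raise ValueError("planted pairs exceed the available genes")
        if self.planted_drugs_per_subtype * self.n_subtypes > self.n_drugs:
            raise ValueError("planted drugs exceed the panel size")


@dataclass
class SimTruth:
    """Planted ground truth: labels, regulatory pairs, DE genes, drugs."""

    labels: pd.Series
    true_met_pairs: set = field(default_factory=set)
    true_mir_pairs: set = field(default_factory=set)
    true_de: dict = field(default_factory=dict)
    true_drugs: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "labels": {s: int(v) for s, v in self.labels.items()},
            "true_met_pairs": sorted(map(list, self.true_met_pairs)),
            "true_mir_pairs": sorted(map(list, self.true_mir_pairs)),
            "true_de": {str(k): sorted(v) for k, v in self.true_de.items()},
            "true_drugs": {str(k): sorted(v) for k, v in self.true_drugs.items()},
        }


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(n)]


def simulate_cohort(cfg: SimConfig):
    """Generate one synthetic cohort.

    Returns ``(mrna, mirna, meth, cpg_annot, target_lists, survival,
    truth)`` where the three matrices are feature x sample DataFrames,
    ``cpg_annot`` is a probe annotation table, ``target_lists`` is a list
    of three ``(name, pair set)`` tuples, ``survival`` a (sample, time,
    event) table and ``truth`` the planted :class:`SimTruth`.
    """
    cfg.validate()
    (rng_lab, rng_expr, rng_met, rng_mir, rng_lists,
     rng_surv, _rng_drug) = _child_rngs(cfg.seed, 7)

    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    genes = [f"GENE{i:05d}" for i in range(cfg.n_genes)]
    probes = [f"cg{i:07d}" for i in range(cfg.n_cpgs)]
    mirnas = [f"miR-{i:04d}" for i in range(cfg.n_mirnas)]

    labels = pd.Series(
        rng_lab.choice(np.arange(1, cfg.n_subtypes + 1), size=cfg.n_samples,
                       p=np.asarray(cfg.subtype_props, float)),
        index=samples, name="subtype")

    # --- gene pools: planted MET genes, planted MIR genes, the rest null
    perm = rng_expr.permutation(cfg.n_genes)
    met_gene_idx = perm[:cfg.n_true_met_pairs]
    mir_gene_idx = perm[cfg.n_true_met_pairs:
                        cfg.n_true_met_pairs + cfg.n_true_mir_pairs]
    other_idx = perm[cfg.n_true_met_pairs + cfg.n_true_mir_pairs:]

    # --- DE genes per subtype, drawn from both regulatory pools so the
    # subtype signal lives in the screened expression blocks
    shift = np.zeros((cfg.n_genes, cfg.n_subtypes))
    true_de: dict[int, set] = {}
    met_chunks = np.array_split(rng_expr.permutation(met_gene_idx),
                                cfg.n_subtypes)
    mir_chunks = np.array_split(rng_expr.permutation(mir_gene_idx),
                                cfg.n_subtypes)
    spare = list(rng_expr.permutation(other_idx))
    for s in range(cfg.n_subtypes):
        idx = list(met_chunks[s]) + list(mir_chunks[s])
        while len(idx) < cfg.de_genes_per_subtype and spare:
            idx.append(spare.pop())
        idx = idx[:cfg.de_genes_per_subtype]
        shift[idx, s] = cfg.effect_size_delta
        true_de[s + 1] = {genes[i] for i in idx}

    # --- expression: baseline mean + subtype shift + noise.  A shared
    # per-sample dysregulation factor inflates the noise of the regulated
    # genes in BOTH blocks (the co-regulated aberrance burden the
    # aberrance stage measures); the factor is normalized so the average
    # noise variance is exactly 1 and the planted correlations stay exact.
    base_mean = rng_expr.uniform(2.0, 10.0, size=cfg.n_genes)
    lab0 = labels.to_numpy() - 1
    noise = rng_expr.standard_normal((cfg.n_genes, cfg.n_samples))
    c = cfg.aberrance_coupling
    if c > 0:
        burden = rng_expr.standard_normal(cfg.n_samples)
        f = np.exp(c * burden - c * c)        # E[f^2] = 1
        regulated = np.concatenate([met_gene_idx, mir_gene_idx])
        noise[regulated] *= f[None, :]
    expr = base_mean[:, None] + shift[:, lab0] + noise
    mrna = pd.DataFrame(expr, index=genes, columns=samples)

    # population moments (exact, not empirical) for correlation planting
    props = np.asarray(cfg.subtype_props, float)
    m1 = shift @ props
    m2 = (shift ** 2) @ props
    pop_mean = base_mean + m1
    pop_sd = np.sqrt(1.0 + m2 - m1 ** 2)
    expr_std = (expr - pop_mean[:, None]) / pop_sd[:, None]

    r = cfg.target_r
    mix = np.sqrt(max(0.0, 1.0 - r * r))

    # --- methylation: planted probes coupled on the logit scale
    probe_center = rng_met.uniform(-1.5, 1.5, size=cfg.n_cpgs)
    probe_scale = 0.5
    mvals = rng_met.standard_normal((cfg.n_cpgs, cfg.n_samples))
    true_met_pairs: set[tuple[str, str]] = set()
    probe_perm = rng_met.permutation(cfg.n_cpgs)
    true_probe_idx = probe_perm[:cfg.n_true_met_pairs]
    for p_i, g_i in zip(true_probe_idx, met_gene_idx):
        mvals[p_i] = r * expr_std[g_i] + mix * rng_met.standard_normal(
            cfg.n_samples)
        true_met_pairs.add((probes[p_i], genes[g_i]))
    meth = pd.DataFrame(
        expit(probe_center[:, None] + probe_scale * mvals),
        index=probes, columns=samples)

    # --- probe annotation; planted probes skew to Island / TSS200
    annot_gene = np.empty(cfg.n_cpgs, dtype=object)
    annot_gene[true_probe_idx] = [genes[i] for i in met_gene_idx]
    null_probe_idx = probe_perm[cfg.n_true_met_pairs:]
    annot_gene[null_probe_idx] = rng_met.choice(genes, size=len(null_probe_idx))
    is_true = np.zeros(cfg.n_cpgs, bool)
    is_true[true_probe_idx] = True
    island = np.where(
        is_true,
        rng_met.choice(io.ISLAND_RELATIONS, cfg.n_cpgs, p=_ISLAND_P_TRUE),
        rng_met.choice(io.ISLAND_RELATIONS, cfg.n_cpgs, p=_ISLAND_P_NULL))
    position = np.where(
        is_true,
        rng_met.choice(io.POSITION_CLASSES, cfg.n_cpgs, p=_POSITION_P_TRUE),
        rng_met.choice(io.POSITION_CLASSES, cfg.n_cpgs, p=_POSITION_P_NULL))
    cpg_annot = pd.DataFrame({
        "probe_id": probes, "gene": annot_gene,
        "island_relation": island, "position_class": position})

    # --- miRNA expression: planted miRNAs coupled to their target genes
    mirna_mean = rng_mir.uniform(4.0, 10.0, size=cfg.n_mirnas)
    mirna_expr = mirna_mean[:, None] + rng_mir.standard_normal(
        (cfg.n_mirnas, cfg.n_samples))
    true_mir_pairs: set[tuple[str, str]] = set()
    mirna_perm = rng_mir.permutation(cfg.n_mirnas)
    true_mirna_idx = mirna_perm[:cfg.n_true_mir_pairs]
    for m_i, g_i in zip(true_mirna_idx, mir_gene_idx):
        mirna_expr[m_i] = mirna_mean[m_i] + r * expr_std[g_i] \
            + mix * rng_mir.standard_normal(cfg.n_samples)
        true_mir_pairs.add((mirnas[m_i], genes[g_i]))
    mirna = pd.DataFrame(mirna_expr, index=mirnas, columns=samples)

    # --- three target lists: all true pairs + per-list decoys
    target_lists = _make_target_lists(cfg, rng_lists, mirnas, genes,
                                      true_mir_pairs)

    # --- survival: exponential event times, exponential censoring
    hazards = np.asarray(cfg.hazard_per_subtype, float)[lab0]
    t_event = rng_surv.exponential(1.0 / hazards)
    if cfg.censor_rate > 0:
        t_cens = rng_surv.exponential(1.0 / cfg.censor_rate,
                                      size=cfg.n_samples)
    else:
        t_cens = np.full(cfg.n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = pd.DataFrame({"sample": samples,
                             "time": np.maximum(time, 1e-8),
                             "event": event})

    truth = SimTruth(labels=labels, true_met_pairs=true_met_pairs,
                     true_mir_pairs=true_mir_pairs, true_de=true_de)
    return mrna, mirna, meth, cpg_annot, target_lists, survival, truth


def _make_target_lists(cfg, rng, mirnas, genes, true_mir_pairs):
    """Three miRNA->gene lists: every true pair in all three, plus
    independently drawn decoys per list and (optionally) decoys shared by
    all three lists so intersection tests can plant known contamination."""
    truth = set(true_mir_pairs)

    def draw_decoys(k, forbidden):
        out = set()
        guard = 0
        while len(out) < k and guard < 50 * (k + 1):
            m = mirnas[rng.integers(len(mirnas))]
            g = genes[rng.integers(len(genes))]
            if (m, g) not in forbidden and (m, g) not in out:
                out.add((m, g))
            guard += 1
        return out

    shared = draw_decoys(cfg.decoy_overlap, truth)
    lists = []
    for name in ("listA", "listB", "listC"):
        decoys = draw_decoys(cfg.decoys_per_list, truth | shared)
        lists.append((name, truth | shared | decoys))
    return lists


def simulate_drug_panel(cfg: SimConfig, labels: pd.Series):
    """Generate the drug-response side of the cohort.

    Returns ``(auc, cellline_expr, true_drugs)``: an AUC matrix (sample x
    drug, NaN where masked missing), an expression matrix for the same
    profiled lines (carrying the subtype shifts so expression is
    predictive of response), and the planted subtype -> drug mapping.
    AUC is log-normal around a per-drug baseline; a planted drug for
    subtype ``s`` is lower by ``drug_effect_log2`` (log2 scale) in the
    samples of ``s``.
    """
    cfg.validate()
    rng = _child_rngs(cfg.seed, 7)[6]
    samples = list(labels.index)
    lab0 = labels.to_numpy() - 1
    drugs = [f"DRUG{j:03d}" for j in range(cfg.n_drugs)]

    drug_perm = rng.permutation(cfg.n_drugs)
    true_drugs: dict[int, set] = {}
    effect = np.zeros((len(samples), cfg.n_drugs))
    pos = 0
    for s in range(cfg.n_subtypes):
        idx = drug_perm[pos:pos + cfg.planted_drugs_per_subtype]
        pos += cfg.planted_drugs_per_subtype
        true_drugs[s + 1] = {drugs[j] for j in idx}
        effect[np.ix_(lab0 == s, idx)] = -cfg.drug_effect_log2

    base_log2 = rng.uniform(-1.5, -0.3, size=cfg.n_drugs)  # AUC ~ 0.35-0.8
    log2auc = (base_log2[None, :] + effect
               + cfg.auc_sd_log2 * rng.standard_normal(
                   (len(samples), cfg.n_drugs)))
    auc = pd.DataFrame(2.0 ** log2auc, index=samples, columns=drugs)

    if cfg.missing_frac > 0:
        mask = rng.random(auc.shape) < cfg.missing_frac
        auc = auc.mask(mask)

    genes = [f"GENE{i:05d}" for i in range(cfg.n_genes)]
    shift = np.zeros((cfg.n_genes, cfg.n_subtypes))
    n_pred = min(50, cfg.n_genes)
    pred_idx = rng.choice(cfg.n_genes, size=n_pred, replace=False)
    for s in range(cfg.n_subtypes):
        block = pred_idx[s::cfg.n_subtypes]
        shift[block, s] = cfg.effect_size_delta
    base = rng.uniform(2.0, 10.0, size=cfg.n_genes)
    expr = (base[:, None] + shift[:, lab0]
            + rng.standard_normal((cfg.n_genes, len(samples))))
    cellline_expr = pd.DataFrame(expr, index=genes, columns=samples)
    return auc, cellline_expr, true_drugs


def write_cohort(outdir: str | Path, mrna, mirna, meth, cpg_annot,
                 target_lists, survival, truth: SimTruth) -> None:
    """Write every cohort artifact in its TSV/JSON exchange format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_omics_matrix(mrna, outdir / "mrna.tsv")
    io.write_omics_matrix(mirna, outdir / "mirna.tsv")
    io.write_omics_matrix(meth, outdir / "meth.tsv")
    io.write_cpg_annotation(cpg_annot, outdir / "cpg_annotation.tsv")
    for name, pairs in target_lists:
        io.write_target_list(pairs, outdir / f"targets_{name}.tsv")
    io.write_survival_table(survival, outdir / "survival.tsv")
    io.write_json(truth.to_json_dict(), outdir / "truth.json")
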