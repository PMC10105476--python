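"""Screening of methylation- and miRNA-correlated genes.

A gene is METcor if its expression is significantly negatively correlated
with the beta value of one of its annotated promoter CpG probes; MIRcor if
significantly negatively correlated with a miRNA predicted to target it by
all three supplied target lists.  Significance uses the variance-
stabilized Fisher transform: z = atanh(r), and z*sqrt(n-3) is compared to
a critical value (default -1.96, a one-sided alpha ~ 0.025 test for
negative correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io

PAIR_COLUMNS = ["regulator", "gene", "kind", "n_eff", "r", "z", "z_std",
                "valid", "significant"]


@dataclass
class ScreenConfig:
    z_crit: float = -1.96
    min_overlap: int = 30
    negative_only: bool = True
    promoter_classes: tuple | None = None  # None = all classes present

    def __post_init__(self):
        if self.negative_only and self.z_crit >= 0:
            raise ValueError("z_crit must be negative when negative_only")
        if self.min_overlap < 4:
            raise ValueError("min_overlap must be >= 4 (sqrt(n-3) guard)")


def pair_cpg_genes(meth: pd.DataFrame, mrna: pd.DataFrame,
                   annot: pd.DataFrame,
                   cfg: ScreenConfig | None = None) -> pd.DataFrame:
    """Candidate CpG-gene pairs: annotation rows whose probe and gene are
    both measured and whose position class is admitted.  Statistics are
    left unfilled (NaN) for :func:`score_pairs`."""
    cfg = cfg or ScreenConfig()
    io.validate_cpg_annotation(annot)
    shared = meth.columns.intersection(mrna.columns)
    if len(shared) == 0:
        raise ValueError(
            "methylation and mRNA matrices share no sample columns")
    if len(shared) < cfg.min_overlap:
        raise ValueError(
            f"only {len(shared)} shared samples between methylation and "
            f"mRNA matrices; need >= min_overlap={cfg.min_overlap}")
    classes = (set(cfg.promoter_classes) if cfg.promoter_classes is not None
               else set(annot["position_class"]))
    keep = (annot["probe_id"].isin(meth.index)
            & annot["gene"].isin(mrna.index)
            & annot["position_class"].isin(classes))
    cand = annot.loc[keep, ["probe_id", "gene"]].rename(
        columns={"probe_id": "regulator"})
    return _empty_stats(cand, kind="CpG")


def pair_mirna_genes(lists, mirna: pd.DataFrame,
                     mrna: pd.DataFrame) -> pd.DataFrame:
    """Candidate miRNA-gene pairs: strict intersection of the three target
    lists, restricted to measured miRNAs and genes."""
    pair_sets = [set(pairs) for _name, pairs in lists]
    if not any(pair_sets):
        raise ValueError("all target lists are empty")
    inter = set.intersection(*pair_sets)
    measured = {(m, g) for m, g in inter
                if m in mirna.index and g in mrna.index}
    if not measured:
        warnings.warn("miRNA target-list intersection is empty after "
                      "restricting to measured features")
    cand = pd.DataFrame(sorted(measured), columns=["regulator", "gene"])
    return _empty_stats(cand, kind="miRNA")


def _empty_stats(cand: pd.DataFrame, kind: str) -> pd.DataFrame:
    cand = cand.copy().reset_index(drop=True)
    cand["kind"] = kind
    for col in ("n_eff", "r", "z", "z_std"):
        cand[col] = np.nan
    cand["valid"] = False
    cand["significant"] = False
    return cand[PAIR_COLUMNS]


def score_pairs(candidates: pd.DataFrame, regulator_mat: pd.DataFrame,
                mrna: pd.DataFrame,
                cfg: ScreenConfig | None = None) -> pd.DataFrame:
    """Fill Pearson r, Fisher z and the standardized score for each pair.

    r is computed on pairwise-complete samples; a pair is valid only when
    it has >= min_overlap complete observations, non-degenerate variance
    on both sides and |r| < 1.  significant = z*sqrt(n-3) < z_crit (and
    r < 0 when negative_only), strict inequality.
    """
    cfg = cfg or ScreenConfig()
    if candidates.empty:
        raise ValueError("candidate pair table is empty")
    shared = regulator_mat.columns.intersection(mrna.columns)
    reg = regulator_mat.loc[:, shared].to_numpy(float)
    exp = mrna.loc[:, shared].to_numpy(float)
    reg_pos = pd.Series(np.arange(len(regulator_mat)),
                        index=regulator_mat.index)
    exp_pos = pd.Series(np.arange(len(mrna)), index=mrna.index)

    out = candidates.copy().reset_index(drop=True)
    ri = reg_pos.reindex(out["regulator"]).to_numpy()
    gi = exp_pos.reindex(out["gene"]).to_numpy()
    if np.isnan(ri).any() or np.isnan(gi).any():
        raise KeyError("candidate table references unmeasured features")
    x = reg[ri.astype(int)]
    y = exp[gi.astype(int)]

    ok = np.isfinite(x) & np.isfinite(y)
    n_eff = ok.sum(axis=1).astype(float)
    xm = np.where(ok, x, 0.0)
    ym = np.where(ok, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = xm.sum(axis=1)
        sy = ym.sum(axis=1)
        sxx = (xm * xm).sum(axis=1)
        syy = (ym * ym).sum(axis=1)
        sxy = (xm * ym).sum(axis=1)
        cov = sxy - sx * sy / n_eff
        vx = sxx - sx * sx / n_eff
        vy = syy - sy * sy / n_eff
        r = cov / np.sqrt(vx * vy)

    valid = ((n_eff >= cfg.min_overlap)
             & np.isfinite(r) & (np.abs(r) < 1.0)
             & (vx > 0) & (vy > 0))
    r = np.where(valid, r, np.nan)
    with np.errstate(invalid="ignore"):
        z = np.arctanh(r)
        z_std = z * np.sqrt(n_eff - 3.0)
    sig = valid & (z_std < cfg.z_crit)
    if cfg.negative_only:
        sig &= r < 0

    out["n_eff"] = n_eff
    out["r"] = r
    out["z"] = z
    out["z_std"] = z_std
    out["valid"] = valid
    out["significant"] = sig
    return out


def collect_regulated_genes(scored: pd.DataFrame):
    """Genes with at least one significant pair, plus a representative
    table keeping each gene's most extreme (minimum z_std) pair."""
    sig = scored.loc[scored["significant"]]
    genes = set(sig["gene"])
    if sig.empty:
        best = sig.copy()
    else:
        best = sig.loc[sig.groupby("gene")["z_std"].idxmin()] \
                  .sort_values("z_std").reset_index(drop=True)
    return genes, best


def region_frequency(scored: pd.DataFrame, annot: pd.DataFrame,
                     universe: pd.DataFrame | None = None) -> pd.DataFrame:
    """Proportion of significant probes vs all probes per island relation
    and per genomic position class (the promoter-region frequency view).

    Returns a long table (dimension, level, prop_significant,
    prop_universe, enrichment)."""
    if universe is None:
        universe = annot
    if not (scored["kind"] == "CpG").all():
        raise ValueError("region_frequency applies to CpG pairs only")
    sig_probes = set(scored.loc[scored["significant"], "regulator"])
    if not sig_probes:
        warnings.warn("no significant probes; frequency table is all zero")
    sig_annot = annot.loc[annot["probe_id"].isin(sig_probes)]
    rows = []
    for dim, levels in (("island_relation", io.ISLAND_RELATIONS),
                        ("position_class", io.POSITION_CLASSES)):
        n_sig = len(sig_annot.drop_duplicates("probe_id"))
        uni = universe.drop_duplicates("probe_id")
        for level in levels:
            p_sig = ((sig_annot.drop_duplicates("probe_id")[dim] == level)
                     .sum() / n_sig) if n_sig else 0.0
            p_uni = (uni[dim] == level).mean() if len(uni) else 0.0
            rows.append({
                "dimension": dim, "level": level,
                "prop_significant": float(p_sig),
                "prop_universe": float(p_uni),
                "enrichment": float(p_sig / p_uni) if p_uni > 0 else np.nan,
            })
    return pd.DataFrame(rows)


def overlap_genes(met_genes: set, mir_genes: set):
    """Intersection of the two regulated gene sets, with the Venn counts."""
    met_genes, mir_genes = set(met_genes), set(mir_genes)
    both = met_genes & mir_genes
    counts = {"met_only": len(met_genes - mir_genes),
              "mir_only": len(mir_genes - met_genes),
              "both": len(both)}
    return both, counts


def write_pair_table(scored: pd.DataFrame, path) -> None:
    scored.to_csv(path, sep="\t", index=False)


def read_pair_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df[PAIR_COLUMNS]
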