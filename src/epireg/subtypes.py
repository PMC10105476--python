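"""Subtype signatures, nearest-template classification, and cross-cohort
concordance.

Signatures are one-vs-rest marker lists (Welch t + BH, ordered by log2
fold change, truncated to the top N).  External cohorts are classified by
nearest template prediction (NTP): cosine distance between a sample's
standardized expression over the union of signature genes and each
subtype's indicator template, with a size-matched random-template
resampling p-value.  Cross-cohort subtype concordance is a one-direction
subclass-mapping screen: enrichment of cohort A's subtype signatures at
the top of cohort B's subtype-vs-rest t-statistic ranking (weighted
Kolmogorov-Smirnov running sum), with label-permutation p-values and BH
over the full subtype x subtype matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class SignatureSet:
    """Per-subtype ranked marker tables (gene, log2fc, t_stat, p, fdr)."""

    tables: dict  # subtype id -> DataFrame ordered by descending log2fc
    top_n: int
    fdr_max: float

    def gene_sets(self) -> dict:
        return {str(s): list(t["gene"]) for s, t in self.tables.items()}

    def all_genes(self) -> list:
        seen: list = []
        for t in self.tables.values():
            seen.extend(t["gene"])
        return seen


def _welch_one_vs_rest(x: np.ndarray, in_group: np.ndarray):
    """Vectorized Welch t-test per row of x for in_group vs rest.

    Returns (delta, t, p) arrays; delta is the mean difference."""
    a = x[:, in_group]
    b = x[:, ~in_group]
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    delta = a.mean(axis=1) - b.mean(axis=1)
    return delta, np.asarray(t), np.asarray(p)


def extract_signatures(expr: pd.DataFrame, labels: pd.Series,
                       top_n: int = 500,
                       fdr_max: float = 0.05) -> SignatureSet:
    """One-vs-rest markers per subtype on log-scale expression.

    A gene qualifies for a subtype when its BH-adjusted two-sided Welch p
    is below ``fdr_max`` and it is up-regulated there (log2FC > 0); a gene
    qualifying in several subtypes is assigned only to the subtype where
    its log2FC is largest, so templates are disjoint.  Each list is
    ordered by descending log2FC and truncated to ``top_n``."""
    shared = expr.columns.intersection(labels.index)
    lab = labels.loc[shared]
    x = expr.loc[:, shared].to_numpy(float)
    subtypes = sorted(lab.unique())
    for s in subtypes:
        if (lab == s).sum() < 2:
            raise ValueError(f"subtype {s} has fewer than 2 samples")

    stats_by_subtype = {}
    for s in subtypes:
        delta, t, p = _welch_one_vs_rest(x, (lab == s).to_numpy())
        p = np.where(np.isfinite(p), p, 1.0)
        fdr = multipletests(p, method="fdr_bh")[1]
        stats_by_subtype[s] = pd.DataFrame({
            "gene": expr.index, "log2fc": delta,
            "t_stat": np.where(np.isfinite(t), t, 0.0), "p": p, "fdr": fdr})

    # assign each qualifying gene to its max-log2FC subtype
    fc = pd.DataFrame({s: d["log2fc"].to_numpy()
                       for s, d in stats_by_subtype.items()},
                      index=expr.index)
    qual = pd.DataFrame({s: ((d["fdr"].to_numpy() < fdr_max)
                             & (d["log2fc"].to_numpy() > 0))
                         for s, d in stats_by_subtype.items()},
                        index=expr.index)
    any_qual = qual.any(axis=1)
    owner = fc.where(qual).loc[any_qual].idxmax(axis=1)

    tables = {}
    for s in subtypes:
        tab = stats_by_subtype[s].set_index("gene") \
            .loc[owner.index[owner == s]].rename_axis("gene").reset_index()
        tab = tab.sort_values(["log2fc", "gene"],
                              ascending=[False, True]).head(top_n)
        tables[s] = tab.reset_index(drop=True)
    return SignatureSet(tables=tables, top_n=top_n, fdr_max=fdr_max)


def ntp_classify(expr: pd.DataFrame, sig: SignatureSet,
                 n_perm: int = 1000, seed: int = 0,
                 min_genes: int = 10) -> pd.DataFrame:
    """Nearest template prediction with gene-resampling significance.

    Expression is standardized per gene across samples; the template for
    subtype s is the indicator of its measured markers and a sample is
    assigned to the template at minimal cosine distance (ties -> smallest
    subtype index).  The p-value is the add-one fraction of ``n_perm``
    size-matched random gene subsets (drawn uniformly from all measured
    genes) whose template is at least as close; BH across samples."""
    subtypes = sorted(sig.tables)
    measured = {s: [g for g in sig.tables[s]["gene"] if g in expr.index]
                for s in subtypes}
    short = {s: g for s, g in measured.items() if len(g) < min_genes}
    if short:
        raise ValueError(
            "signature coverage below min_genes for subtype(s): "
            + "; ".join(f"{s} has {len(g)} measured of "
                        f"{len(sig.tables[s])}" for s, g in short.items()))
    union = list(expr.index)
    x = expr.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    x = (x - mu) / sd
    norms = np.linalg.norm(x, axis=0)
    norms[norms == 0] = 1.0
    gene_pos = {g: i for i, g in enumerate(union)}

    dist = np.empty((len(subtypes), x.shape[1]))
    for si, s in enumerate(subtypes):
        idx = [gene_pos[g] for g in measured[s]]
        dist[si] = 1.0 - x[idx].sum(axis=0) / (np.sqrt(len(idx)) * norms)
    pred_idx = dist.argmin(axis=0)            # argmin -> smallest index on ties
    d_obs = dist[pred_idx, np.arange(x.shape[1])]

    rng = np.random.default_rng(seed)
    pvals = np.empty(x.shape[1])
    for si, s in enumerate(subtypes):
        cols = np.flatnonzero(pred_idx == si)
        if cols.size == 0:
            continue
        m = len(measured[s])
        rand = np.zeros((n_perm, len(union)))
        for row in range(n_perm):
            rand[row, rng.choice(len(union), size=m, replace=False)] = 1.0
        d_rand = 1.0 - (rand @ x[:, cols]) / (np.sqrt(m) * norms[cols])
        pvals[cols] = (1.0 + (d_rand <= d_obs[cols]).sum(axis=0)) \
            / (n_perm + 1.0)

    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "sample": expr.columns,
        "subtype": [subtypes[i] for i in pred_idx],
        "distance": d_obs, "p": pvals, "fdr": fdr,
    }).reset_index(drop=True)


def _enrichment_score(ranked_t: np.ndarray, in_set: np.ndarray) -> float:
    """Weighted KS running-sum enrichment of ``in_set`` genes at the top
    of a descending t-ranking (weights = |t|)."""
    w = np.abs(ranked_t) * in_set
    nr = w.sum()
    n_miss = (~in_set.astype(bool)).sum()
    if nr == 0 or n_miss == 0:
        return 0.0
    p_hit = np.cumsum(w) / nr
    p_miss = np.cumsum(~in_set.astype(bool)) / n_miss
    return float(np.max(p_hit - p_miss))


def _group_t_matrix(x: np.ndarray, lab: np.ndarray, subtypes) -> np.ndarray:
    """Welch t per gene for each subtype vs rest; rows = subtypes."""
    out = np.empty((len(subtypes), x.shape[0]))
    for i, s in enumerate(subtypes):
        _d, t, _p = _welch_one_vs_rest(x, lab == s)
        out[i] = np.where(np.isfinite(t), t, 0.0)
    return out


def submap_concordance(expr_a: pd.DataFrame, labels_a: pd.Series,
                       expr_b: pd.DataFrame, labels_b: pd.Series,
                       n_perm: int = 1000, seed: int = 0,
                       top_n: int = 500, fdr_max: float = 0.05):
    """Subclass-mapping concordance screen between two cohorts.

    Entry (i, j) tests whether cohort A's subtype-i signature is enriched
    at the top of cohort B's subtype-j-vs-rest t ranking.  Returns
    ``(p_raw, p_adj)`` DataFrames (BH over all entries); both below 0.05
    is the matched-subtype decision rule."""
    for lab, name in ((labels_a, "A"), (labels_b, "B")):
        sizes = lab.value_counts()
        if len(sizes) < 2 or (sizes < 2).any():
            raise ValueError(f"cohort {name} needs >= 2 subtypes "
                             "with >= 2 samples each")
    sig_a = extract_signatures(expr_a, labels_a, top_n=top_n,
                               fdr_max=fdr_max)
    subtypes_a = sorted(sig_a.tables)
    subtypes_b = sorted(labels_b.loc[labels_b.index.intersection(
        expr_b.columns)].unique())

    shared = expr_b.columns.intersection(labels_b.index)
    xb = expr_b.loc[:, shared].to_numpy(float)
    lab_b = labels_b.loc[shared].to_numpy()
    genes_b = list(expr_b.index)
    gene_pos = {g: i for i, g in enumerate(genes_b)}

    set_masks = {}
    for i in subtypes_a:
        present = [gene_pos[g] for g in sig_a.tables[i]["gene"]
                   if g in gene_pos]
        if len(present) < 10:
            warnings.warn(f"signature {i} has <10 genes measured in "
                          "cohort B; p set to 1")
            set_masks[i] = None
        else:
            mask = np.zeros(len(genes_b), bool)
            mask[present] = True
            set_masks[i] = mask

    def es_matrix(lab: np.ndarray) -> np.ndarray:
        tmat = _group_t_matrix(xb, lab, subtypes_b)
        es = np.zeros((len(subtypes_a), len(subtypes_b)))
        for j in range(len(subtypes_b)):
            order = np.argsort(-tmat[j], kind="stable")
            t_sorted = tmat[j][order]
            for ii, i in enumerate(subtypes_a):
                if set_masks[i] is None:
                    es[ii, j] = np.nan
                    continue
                es[ii, j] = _enrichment_score(t_sorted, set_masks[i][order])
        return es

    es_obs = es_matrix(lab_b)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(es_obs)
    for _ in range(n_perm):
        es_p = es_matrix(rng.permutation(lab_b))
        exceed += (es_p >= es_obs)
    p_raw = (1.0 + exceed) / (n_perm + 1.0)
    p_raw[np.isnan(es_obs)] = 1.0

    flat_adj = multipletests(p_raw.ravel(), method="fdr_bh")[1]
    p_adj = np.maximum(flat_adj.reshape(p_raw.shape), p_raw)
    idx = [f"A{i}" for i in subtypes_a]
    cols = [f"B{j}" for j in subtypes_b]
    return (pd.DataFrame(p_raw, index=idx, columns=cols),
            pd.DataFrame(p_adj, index=idx, columns=cols))
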