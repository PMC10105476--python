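"""Single-sample gene-set enrichment (ssGSEA) and subtype comparisons.

Per sample, genes are ranked by expression (average ranks on ties) and a
rank-weighted running sum is accumulated along the list ordered from the
most to the least expressed gene: the in-set cumulative uses weights
rank^alpha (normalized by the in-set weight total) and the out-of-set
cumulative is uniform; the enrichment score is the sum of their
differences over all positions.  alpha = 0 reduces to the classic
unweighted KS running-sum.  Scores are rank-based, hence invariant to any
monotone per-sample transform of expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class SsgseaParams:
    alpha: float = 0.25
    normalize: bool = True   # divide all scores by the global max - min

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def ssgsea_scores(expr: pd.DataFrame, sets: dict,
                  params: SsgseaParams | None = None) -> pd.DataFrame:
    """Sample x set enrichment score matrix.

    ``sets`` maps names to gene lists; sets retaining fewer than 2
    measured genes are skipped with a warning."""
    params = params or SsgseaParams()
    genes = list(expr.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    usable = {}
    for name, members in sets.items():
        idx = [gene_pos[g] for g in dict.fromkeys(members) if g in gene_pos]
        if len(idx) < 2:
            warnings.warn(f"gene set {name!r} has <2 measured genes; skipped")
            continue
        if len(idx) >= n_genes:
            warnings.warn(f"gene set {name!r} covers every measured gene; "
                          "skipped")
            continue
        usable[name] = np.asarray(idx)
    if not usable:
        raise ValueError("no usable gene sets after filtering")

    x = expr.to_numpy(float)
    scores = np.empty((expr.shape[1], len(usable)))
    set_masks = {name: np.zeros(n_genes, bool) for name in usable}
    for name, idx in usable.items():
        set_masks[name][idx] = True

    for j in range(expr.shape[1]):
        col = x[:, j]
        ranks = stats.rankdata(col)                 # highest expr -> rank N
        order = np.argsort(-col, kind="stable")     # descending walk
        w = ranks[order] ** params.alpha
        for si, (name, _idx) in enumerate(usable.items()):
            inset = set_masks[name][order]
            w_in = np.where(inset, w, 0.0)
            p_in = np.cumsum(w_in) / w_in.sum()
            p_out = np.cumsum(~inset) / (n_genes - inset.sum())
            scores[j, si] = np.sum(p_in - p_out)

    out = pd.DataFrame(scores, index=expr.columns, columns=list(usable))
    if params.normalize:
        rng_ = out.to_numpy().max() - out.to_numpy().min()
        if rng_ > 0:
            out = out / rng_
    return out


def compare_scores_by_subtype(scores: pd.DataFrame, labels: pd.Series):
    """Per-set Kruskal-Wallis test across subtypes with BH adjustment.

    Returns a DataFrame (set, H, p, fdr, median_<subtype>...); subtypes
    with fewer than 2 samples are excluded with a warning."""
    shared = scores.index.intersection(labels.index)
    lab = labels.loc[shared]
    sc = scores.loc[shared]
    sizes = lab.value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding subtype(s) with <2 samples: {small}")
        keep = ~lab.isin(small)
        lab, sc = lab[keep], sc.loc[keep]
    subtypes = sorted(lab.unique())
    if len(subtypes) < 2:
        raise ValueError("need >= 2 subtypes with >= 2 samples")

    rows = []
    for name in sc.columns:
        groups = [sc.loc[lab == s, name].to_numpy() for s in subtypes]
        h, p = stats.kruskal(*groups)
        row = {"set": name, "H": float(h), "p": float(p)}
        for s, g in zip(subtypes, groups):
            row[f"median_{s}"] = float(np.median(g))
        rows.append(row)
    res = pd.DataFrame(rows)
    res["fdr"] = multipletests(res["p"], method="fdr_bh")[1]
    return res
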