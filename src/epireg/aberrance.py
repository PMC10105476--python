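"""Per-sample aberrant-expression frequencies and their co-regulation.

For a regulated gene set (METcor or MIRcor), each gene's lower and upper
quartiles are computed across samples; a gene is aberrantly high in a
sample when its value strictly exceeds the upper quantile and aberrantly
low when strictly below the lower one.  A sample's profile is the
fraction of set genes that are high / low / either.  Co-regulation is the
Pearson correlation of these per-sample frequencies between the two sets.

Quantiles are per gene across samples (not per sample across genes):
ranking within each sample would force identical 25% high / 25% low
fractions in every sample and make the cross-sample correlation
degenerate, so the per-gene reading is the one under which the statistic
is informative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AberranceConfig:
    q_low: float = 0.25
    q_high: float = 0.75
    quantile_rule: str = "linear"  # numpy interpolation method

    def __post_init__(self):
        if not (0.0 < self.q_low < self.q_high < 1.0):
            raise ValueError("need 0 < q_low < q_high < 1")


def aberrance_profile(expr: pd.DataFrame, genes, label: str,
                      cfg: AberranceConfig | None = None) -> pd.DataFrame:
    """Per-sample high/low/total aberrance frequencies for one gene set.

    Constant genes contribute to neither tail (Q1 = Q3 and the
    inequalities are strict)."""
    cfg = cfg or AberranceConfig()
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    measured = [g for g in expr.index if g in set(genes)]
    if not measured:
        raise ValueError(f"no measured genes in set {label!r}")
    x = expr.loc[measured].to_numpy(float)
    q1 = np.quantile(x, cfg.q_low, axis=1, method=cfg.quantile_rule)
    q3 = np.quantile(x, cfg.q_high, axis=1, method=cfg.quantile_rule)
    high = (x > q3[:, None]).sum(axis=0) / len(measured)
    low = (x < q1[:, None]).sum(axis=0) / len(measured)
    return pd.DataFrame({
        "sample": expr.columns,
        "set": label,
        "freq_high": high,
        "freq_low": low,
        "freq_total": high + low,
    }).reset_index(drop=True)


def coregulation_correlation(p_met: pd.DataFrame, p_mir: pd.DataFrame):
    """Pearson correlation of total aberrance frequencies between the two
    profiles, plus the full 4x4 pairwise matrix over {MET_high, MET_low,
    MIR_high, MIR_low} with two-sided p-values.

    Returns ``(r, p, corr_matrix, p_matrix)``."""
    a = p_met.set_index("sample")
    b = p_mir.set_index("sample")
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples between profiles")
    a, b = a.loc[shared], b.loc[shared]
    r, p = stats.pearsonr(a["freq_total"], b["freq_total"])

    vecs = {
        "MET_high": a["freq_high"], "MET_low": a["freq_low"],
        "MIR_high": b["freq_high"], "MIR_low": b["freq_low"],
    }
    names = list(vecs)
    cm = pd.DataFrame(np.eye(4), index=names, columns=names)
    pm = pd.DataFrame(np.zeros((4, 4)), index=names, columns=names)
    for i, ni in enumerate(names):
        for nj in names[i + 1:]:
            rij, pij = stats.pearsonr(vecs[ni], vecs[nj])
            cm.loc[ni, nj] = cm.loc[nj, ni] = rij
            pm.loc[ni, nj] = pm.loc[nj, ni] = pij
    return float(r), float(p), cm, pm
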