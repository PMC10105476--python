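"""Drug-sensitivity screening from dose-response AUC matrices.

AUC (area under the dose-response curve) is the sensitivity readout:
lower AUC = more sensitive.  The stage chain is: filter drugs by
missingness and impute the remainder by k-nearest-neighbor cell lines;
predict per-tumor AUC by per-drug ridge regression on cell-line
expression; call a drug subtype-specific when the log2 ratio of every
other subtype's mean predicted AUC to that subtype's mean exceeds a
threshold (default 0.05) for all comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold


@dataclass
class DrugScreenConfig:
    missing_max: float = 0.20
    knn_k: int = 5
    ridge_lambda_grid: tuple = (0.01, 0.1, 1.0, 10.0, 100.0)
    cv_folds: int = 10
    ratio_threshold: float = 0.05
    min_shared_genes: int = 200
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.missing_max < 1.0):
            raise ValueError("missing_max must lie in (0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be positive")


@dataclass
class DrugScreenResult:
    table: pd.DataFrame            # drug, per-subtype means, ratios, call
    assignments: dict = field(default_factory=dict)  # subtype -> drug set


def filter_and_impute(auc: pd.DataFrame,
                      cfg: DrugScreenConfig | None = None) -> pd.DataFrame:
    """Drop drugs with missingness strictly above ``missing_max`` and
    fill remaining gaps by the unweighted mean of the drug's value in the
    k nearest cell lines (Euclidean distance over per-drug z-scored,
    mutually observed drugs; neighbors lacking the drug are skipped and
    the next nearest used).  Observed entries are never altered."""
    cfg = cfg or DrugScreenConfig()
    if len(auc) < cfg.knn_k + 1:
        raise ValueError(f"need >= knn_k+1={cfg.knn_k + 1} cell lines")
    if (auc.dropna(how="all").to_numpy() <= 0).any() and \
            np.nanmin(auc.to_numpy()) <= 0:
        raise ValueError("observed AUC values must be positive")
    frac_missing = auc.isna().mean(axis=0)
    kept = auc.loc[:, frac_missing <= cfg.missing_max].copy()
    if kept.isna().to_numpy().sum() == 0:
        return kept

    x = kept.to_numpy(float)
    obs = np.isfinite(x)
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd

    # pairwise cell-line distances over mutually observed drugs
    zf = np.where(obs, z, 0.0)
    of = obs.astype(float)
    sq = zf ** 2
    shared = of @ of.T
    d2 = (sq @ of.T) + (of @ sq.T) - 2.0 * (zf @ zf.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(np.maximum(d2, 0.0) / shared)
    dist[shared == 0] = np.inf
    np.fill_diagonal(dist, np.inf)

    filled = x.copy()
    col_means = mu
    for i in np.flatnonzero(~obs.all(axis=1)):
        order = np.argsort(dist[i], kind="stable")
        if not np.isfinite(dist[i][order[0]]):
            warnings.warn(f"cell line {kept.index[i]!r} shares no observed "
                          "drugs with any other; using column means")
            filled[i, ~obs[i]] = col_means[~obs[i]]
            continue
        for j in np.flatnonzero(~obs[i]):
            donors = [c for c in order
                      if obs[c, j] and np.isfinite(dist[i, c])]
            if donors:
                filled[i, j] = x[donors[:cfg.knn_k], j].mean()
            else:
                filled[i, j] = col_means[j]
    return pd.DataFrame(filled, index=kept.index, columns=kept.columns)


def predict_sensitivity(cellline_expr: pd.DataFrame,
                        auc_complete: pd.DataFrame,
                        tumor_expr: pd.DataFrame,
                        cfg: DrugScreenConfig | None = None):
    """Per-drug ridge regression of AUC on cell-line expression, with the
    penalty chosen per drug by cross-validated MSE, applied to tumors.

    Expression matrices are z-scored per gene within their own dataset
    (a minimal cross-platform homogenization).  Returns ``(pred, info)``:
    predicted sample x drug AUCs and a per-drug table (chosen lambda,
    constant-prediction flag)."""
    cfg = cfg or DrugScreenConfig()
    shared_genes = cellline_expr.index.intersection(tumor_expr.index)
    if len(shared_genes) < cfg.min_shared_genes:
        raise ValueError(f"only {len(shared_genes)} shared genes; need >= "
                         f"{cfg.min_shared_genes}")
    lines = cellline_expr.columns.intersection(auc_complete.index)

    def zscore_rows(m: pd.DataFrame) -> np.ndarray:
        a = m.to_numpy(float)
        mu = a.mean(axis=1, keepdims=True)
        sd = a.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (a - mu) / sd

    x_train = zscore_rows(cellline_expr.loc[shared_genes, lines]).T
    x_tumor = zscore_rows(tumor_expr.loc[shared_genes]).T
    y_all = auc_complete.loc[lines]

    n_splits = min(cfg.cv_folds, len(lines))
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=cfg.seed)
    folds = list(kf.split(x_train))

    preds = {}
    info_rows = []
    for drug in y_all.columns:
        y = y_all[drug].to_numpy(float)
        if y.std() == 0:
            preds[drug] = np.full(x_tumor.shape[0], y[0])
            info_rows.append({"drug": drug, "lambda": np.nan,
                              "constant": True})
            continue
        best_lam, best_mse = None, np.inf
        for lam in cfg.ridge_lambda_grid:
            mse = 0.0
            for tr, te in folds:
                model = Ridge(alpha=lam).fit(x_train[tr], y[tr])
                resid = y[te] - model.predict(x_train[te])
                mse += float(resid @ resid)
            if mse < best_mse:
                best_lam, best_mse = lam, mse
        model = Ridge(alpha=best_lam).fit(x_train, y)
        preds[drug] = model.predict(x_tumor)
        info_rows.append({"drug": drug, "lambda": best_lam,
                          "constant": False})
    pred = pd.DataFrame(preds, index=tumor_expr.columns)
    return pred, pd.DataFrame(info_rows)


def subtype_specific_drugs(pred_auc: pd.DataFrame, labels: pd.Series,
                           cfg: DrugScreenConfig | None = None
                           ) -> DrugScreenResult:
    """Call subtype-specific drugs by the log2 mean-ratio rule.

    For drug means m_s per subtype, the drug belongs to subtype s iff
    log2(m_t / m_s) > ratio_threshold for every other subtype t; at most
    one subtype can satisfy this per drug."""
    cfg = cfg or DrugScreenConfig()
    shared = pred_auc.index.intersection(labels.index)
    lab = labels.loc[shared]
    sizes = lab.value_counts()
    if (sizes < 2).any():
        raise ValueError("every subtype needs >= 2 samples")
    subtypes = sorted(lab.unique())

    means = pred_auc.loc[shared].groupby(lab).mean()  # subtype x drug
    rows = []
    assignments: dict = {s: set() for s in subtypes}
    for drug in pred_auc.columns:
        m = means[drug]
        row = {"drug": drug}
        for s in subtypes:
            row[f"mean_{s}"] = float(m[s])
        if (m <= 0).any():
            warnings.warn(f"drug {drug!r} has a non-positive subtype mean; "
                          "skipped")
            row["assigned"] = None
            rows.append(row)
            continue
        assigned = None
        for s in subtypes:
            ratios = np.log2(m.drop(index=s) / m[s])
            if (ratios > cfg.ratio_threshold).all():
                assigned = s
                break
        row["assigned"] = assigned
        row["min_log2_ratio"] = float(
            min(np.log2(m.drop(index=s0) / m[s0]).min()
                for s0 in [assigned]) if assigned is not None else np.nan)
        if assigned is not None:
            assignments[assigned].add(drug)
        rows.append(row)
    return DrugScreenResult(table=pd.DataFrame(rows),
                            assignments=assignments)


def compare_named_drugs(pred_auc: pd.DataFrame, labels: pd.Series,
                        drug_names) -> pd.DataFrame:
    """Kruskal-Wallis comparison of predicted AUC across subtypes for a
    panel of named drugs (e.g. first-line chemotherapies)."""
    shared = pred_auc.index.intersection(labels.index)
    lab = labels.loc[shared]
    subtypes = sorted(lab.unique())
    if len(subtypes) < 2:
        raise ValueError("need >= 2 subtypes present")
    missing = [d for d in drug_names if d not in pred_auc.columns]
    if missing:
        warnings.warn(f"drug(s) not in the AUC matrix: {missing}")
    rows = []
    for drug in drug_names:
        if drug in missing:
            continue
        groups = [pred_auc.loc[shared][drug][lab == s].to_numpy()
                  for s in subtypes]
        h, p = stats.kruskal(*groups)
        row = {"drug": drug, "H": float(h), "p": float(p)}
        for s, g in zip(subtypes, groups):
            row[f"mean_{s}"] = float(g.mean())
        rows.append(row)
    return pd.DataFrame(rows)
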