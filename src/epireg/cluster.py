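"""Joint latent-factor clustering of multiple expression blocks.

The two regulated-gene expression blocks (and, in principle, any number
of blocks) are stacked and modeled with a Gaussian latent factor model

    x_j = W z_j + e_j,    z_j ~ N(0, I_q),   e_j ~ N(0, diag(psi)),

with q = k - 1 latent factors for k clusters.  The model is fitted by a
deterministic EM (MAP-EM with a per-feature noise-scaled Gaussian ridge
prior on the loadings, so the tracked log-posterior objective is monotone
non-decreasing every iteration).  Cluster labels come from k-means on the
posterior factor scores E[Z|X]; the number of clusters is selected by BIC
over a candidate range, with a deviance ratio trace reported alongside.

This is a deterministic analog of Bayesian integrative clustering
(iClusterBayes-style): same contract — joint latent space over omics
blocks, cluster count by BIC — without MCMC.  Initialization is an SVD of
the stacked data, so fits are reproducible; the only randomness is the
seeded k-means restart schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

_PSI_FLOOR = 1e-8


@dataclass
class ClusterConfig:
    k_range: tuple = (2, 3, 4, 5, 6)
    max_iter: int = 200
    tol: float = 1e-6
    ridge_lambda: float = 1e-3
    kmeans_restarts: int = 50
    seed: int = 0

    def __post_init__(self):
        if min(self.k_range) < 2:
            raise ValueError("k_range entries must be >= 2")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class SubtypeModel:
    k: int
    loadings: dict            # block name -> feature x q DataFrame
    latent: pd.DataFrame      # q x sample posterior means E[Z|X]
    noise_var: pd.Series      # per stacked feature
    labels: pd.Series         # sample -> 1..k
    loglik: float
    bic: dict                 # k -> BIC over every candidate fitted
    deviance_ratio: dict      # k -> 1 - RSS/RSS0
    converged: bool
    seed: int
    objective_trace: list = field(default_factory=list)


def _standardize_block(block: pd.DataFrame) -> pd.DataFrame:
    x = block.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 1e-10
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature(s) "
                      "before clustering")
    z = (x[keep] - mu[keep]) / sd[keep]
    return pd.DataFrame(z, index=block.index[keep], columns=block.columns)


def _em_factor_model(x: np.ndarray, q: int, cfg: ClusterConfig):
    """MAP-EM for the factor model on standardized data x (p x n).

    Returns (W, psi, ez, loglik, objective_trace, converged)."""
    p, n = x.shape
    lam = cfg.ridge_lambda

    # deterministic SVD initialization
    u, s, _vt = np.linalg.svd(x, full_matrices=False)
    w = u[:, :q] * (s[:q] / np.sqrt(n))
    psi = np.maximum(1.0 - (w ** 2).sum(axis=1), 0.05)

    xxt_diag = (x * x).sum(axis=1)
    trace: list[float] = []
    converged = False
    ll = -np.inf
    for _ in range(cfg.max_iter):
        # E-step
        wp = w / psi[:, None]                      # Psi^-1 W
        m = np.eye(q) + w.T @ wp                   # I + W' Psi^-1 W
        minv = np.linalg.inv(m)
        ez = minv @ (wp.T @ x)                     # q x n
        g = n * minv + ez @ ez.T                   # sum E[zz']

        # log-likelihood (Woodbury) and penalized objective
        sign, logdet_m = np.linalg.slogdet(m)
        logdet_sigma = np.log(psi).sum() + logdet_m
        six = x / psi[:, None] - wp @ (minv @ (wp.T @ x))
        quad = float((x * six).sum())
        ll = -0.5 * (n * (p * np.log(2 * np.pi) + logdet_sigma) + quad)
        obj = ll - 0.5 * lam * ((w ** 2) / psi[:, None]).sum() \
            - 0.5 * q * np.log(psi).sum()
        trace.append(obj)
        if len(trace) > 1:
            denom = max(1.0, abs(trace[-2]))
            if (trace[-1] - trace[-2]) / denom < cfg.tol:
                converged = True
                break

        # M-step (MAP): w_i = a_i (G + lam I)^-1, per-feature noise
        a = x @ ez.T                               # p x q
        glam = g + lam * np.eye(q)
        w = np.linalg.solve(glam, a.T).T
        quad_i = xxt_diag - 2 * (w * a).sum(axis=1) \
            + np.einsum("iq,qr,ir->i", w, glam, w)
        psi = np.maximum(quad_i / (n + q), _PSI_FLOOR)

    return w, psi, ez, ll, trace, converged


def _relabel(raw_labels: np.ndarray, ez: np.ndarray, k: int) -> np.ndarray:
    """Deterministic relabeling: descending cluster size, ties broken by
    ascending mean of the first latent coordinate; output labels 1..k."""
    order_key = []
    for c in range(k):
        mask = raw_labels == c
        order_key.append((-int(mask.sum()),
                          float(ez[0, mask].mean()) if mask.any() else np.inf,
                          c))
    mapping = {c: i + 1 for i, (_, _, c) in enumerate(sorted(order_key))}
    return np.array([mapping[c] for c in raw_labels])


def fit_latent_model(blocks, k: int,
                     cfg: ClusterConfig | None = None) -> SubtypeModel:
    """Fit the joint factor model with k clusters (k-1 factors) on a list
    of (name, feature x sample DataFrame) blocks sharing sample columns."""
    cfg = cfg or ClusterConfig()
    named = [(name, _standardize_block(b)) for name, b in blocks]
    cols = named[0][1].columns
    for name, b in named[1:]:
        if not b.columns.equals(cols):
            raise ValueError(f"block {name!r} sample columns differ")
    n = len(cols)
    if not (2 <= k < n):
        raise ValueError(f"k must satisfy 2 <= k < n_samples={n}")

    x = np.vstack([b.to_numpy() for _name, b in named])
    q = k - 1
    w, psi, ez, ll, trace, converged = _em_factor_model(x, q, cfg)
    # canonical factor signs (largest-|loading| component positive) so the
    # relabeling rule is invariant to sample-column permutation
    for j in range(q):
        if w[np.argmax(np.abs(w[:, j])), j] < 0:
            w[:, j] = -w[:, j]
            ez[j, :] = -ez[j, :]
    if not converged:
        warnings.warn(f"EM did not converge within {cfg.max_iter} iterations "
                      f"for k={k}; returning best iterate")

    km = KMeans(n_clusters=k, n_init=cfg.kmeans_restarts,
                random_state=cfg.seed)
    raw = km.fit_predict(ez.T)
    labels = pd.Series(_relabel(raw, ez, k), index=cols, name="subtype")

    p_total = x.shape[0]
    p_eff = p_total * q + p_total
    bic = -2.0 * ll + p_eff * np.log(n * p_total)
    rss = float(((x - w @ ez) ** 2).sum())
    rss0 = float((x ** 2).sum())

    loadings = {}
    offset = 0
    feat_index = []
    for name, b in named:
        loadings[name] = pd.DataFrame(w[offset:offset + len(b)],
                                      index=b.index)
        feat_index.extend(b.index)
        offset += len(b)
    return SubtypeModel(
        k=k, loadings=loadings,
        latent=pd.DataFrame(ez, columns=cols),
        noise_var=pd.Series(psi, index=feat_index),
        labels=labels, loglik=ll,
        bic={k: float(bic)}, deviance_ratio={k: 1.0 - rss / rss0},
        converged=converged, seed=cfg.seed, objective_trace=trace)


def select_k(blocks, cfg: ClusterConfig | None = None) -> SubtypeModel:
    """Fit every k in cfg.k_range and return the argmin-BIC model with the
    full BIC and deviance-ratio traces attached."""
    cfg = cfg or ClusterConfig()
    fits = {k: fit_latent_model(blocks, k, cfg) for k in cfg.k_range}
    bic = {k: m.bic[k] for k, m in fits.items()}
    dev = {k: m.deviance_ratio[k] for k, m in fits.items()}
    best = fits[min(bic, key=bic.get)]
    best.bic = bic
    best.deviance_ratio = dev
    return best


def cross_tabulate(labels: pd.Series, clinical: pd.DataFrame) -> dict:
    """Association of cluster labels with each categorical clinical
    variable: contingency table + chi-square p (Fisher's exact for 2x2
    tables with any expected cell < 5)."""
    shared = labels.index.intersection(clinical.index)
    if len(shared) == 0:
        raise ValueError("labels and clinical table share no samples")
    lab = labels.loc[shared]
    out = {}
    for var in clinical.columns:
        col = clinical.loc[shared, var].dropna()
        if col.nunique() < 2:
            warnings.warn(f"clinical variable {var!r} has a single level; "
                          "skipped")
            continue
        table = pd.crosstab(lab.loc[col.index], col)
        arr = table.to_numpy()
        expected = stats.contingency.expected_freq(arr)
        if arr.shape == (2, 2) and (expected <= 5).any():
            _odds, p = stats.fisher_exact(arr)
            test = "fisher"
        else:
            _chi2, p, _dof, _exp = stats.chi2_contingency(arr)
            test = "chi2"
        out[var] = {"table": table, "test": test, "p": float(p)}
    return out
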