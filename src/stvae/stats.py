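"""Permutation tests, cross-validated classification and per-gene regression
for evaluating feature spaces against a reference partition.

PERMANOVA uses Anderson's pseudo-F computed from the pairwise Euclidean
distance matrix in its sums-of-squared-distances form (equivalent to the
Gower-centered inner-product form); PERMDISP is a Levene-type permutation
ANOVA on each point's distance to its group centroid. Both are run pairwise
over label pairs with free permutation of the pooled samples and BH-FDR
correction across pairs. Permutation p-values are (#{F_perm >= F_obs} + 1) /
(n_perm + 1), so they are bounded below by 1/(n_perm + 1).
"""

from __future__ import annotations

import itertools
import warnings
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_fdr",
    "pairwise_permanova",
    "pairwise_permdisp",
    "rf_cv_balanced_accuracy",
    "ridge_predict_genes",
    "permanova_pseudo_f",
]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# PERMANOVA / PERMDISP

def _pair_sq_dist(X: np.ndarray) -> np.ndarray:
    from sklearn.metrics.pairwise import euclidean_distances

    D = euclidean_distances(X)
    return D ** 2


def permanova_pseudo_f(D2: np.ndarray, membership: np.ndarray) -> float:
    """Two-group pseudo-F from a squared-distance matrix.

    SS_total = sum_{i<j} d2 / n; SS_within = sum_g (sum_{i<j in g} d2) / n_g;
    F = (SS_between / (a-1)) / (SS_within / (n-a)).
    """
    n = D2.shape[0]
    u = membership.astype(np.float64)
    n1 = u.sum()
    n0 = n - n1
    ss_total = D2.sum() / (2.0 * n)
    ss_1 = u @ D2 @ u / 2.0
    ss_0 = (1 - u) @ D2 @ (1 - u) / 2.0
    ss_within = ss_1 / n1 + ss_0 / n0
    ss_between = ss_total - ss_within
    a = 2
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _perm_pvalue(f_obs: float, f_perm: np.ndarray) -> float:
    return (np.sum(f_perm >= f_obs - 1e-12) + 1.0) / (len(f_perm) + 1.0)


def _pairs(labels: np.ndarray):
    uniq = pd.unique(labels)
    counts = {l: int(np.sum(labels == l)) for l in uniq}
    for a, b in itertools.combinations(uniq, 2):
        if counts[a] < 2 or counts[b] < 2:
            warnings.warn(f"pair ({a}, {b}) skipped: a group has < 2 members")
            continue
        yield a, b, counts[a], counts[b]


def _two_group_indicators(n: int, n1: int, n_perm: int,
                          rng: np.random.Generator,
                          exhaustive_limit: int = 10000) -> tuple[np.ndarray, bool]:
    """Permutation indicator matrix (P, n); enumerates all assignments
    exactly when the pair is small enough."""
    total = comb(n, n1)
    if total <= min(n_perm, exhaustive_limit):
        U = np.zeros((total, n))
        for r, pos in enumerate(itertools.combinations(range(n), n1)):
            U[r, list(pos)] = 1.0
        return U, True
    U = np.zeros((n_perm, n))
    for r in range(n_perm):
        U[r, rng.permutation(n)[:n1]] = 1.0
    return U, False


def pairwise_permanova(features: np.ndarray, labels: np.ndarray,
                       n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Pairwise two-group PERMANOVA over all label pairs, BH-corrected.

    ``features`` are expected already standardized. Small pairs fall back to
    exact enumeration over all label assignments.
    """
    X = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    rng = np.random.default_rng([seed, 503])
    rows = []
    for a, b, na, nb in _pairs(labels):
        sel = (labels == a) | (labels == b)
        Xp = X[sel]
        u_obs = (labels[sel] == a).astype(np.float64)
        D2 = _pair_sq_dist(Xp)
        f_obs = permanova_pseudo_f(D2, u_obs)
        U, exact = _two_group_indicators(len(Xp), int(u_obs.sum()), n_perm, rng)
        # vectorised: SS1 = u D2 u / 2 etc. for all permutations at once
        n = len(Xp)
        n1 = u_obs.sum()
        n0 = n - n1
        ss_total = D2.sum() / (2.0 * n)
        UD = U @ D2
        ss1 = np.einsum("pn,pn->p", UD, U) / 2.0
        V = 1.0 - U
        VD = V @ D2
        ss0 = np.einsum("pn,pn->p", VD, V) / 2.0
        ss_w = ss1 / n1 + ss0 / n0
        f_perm = (ss_total - ss_w) / (ss_w / (n - 2))
        if exact:
            p = float(np.mean(f_perm >= f_obs - 1e-12))
        else:
            p = _perm_pvalue(f_obs, f_perm)
        rows.append({"label_a": a, "label_b": b, "statistic": f_obs, "p": p,
                     "n_a": na, "n_b": nb, "test": "permanova"})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = np.maximum(bh_fdr(table["p"].to_numpy()),
                                table["p"].to_numpy())
    return table


def pairwise_permdisp(features: np.ndarray, labels: np.ndarray,
                      n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Pairwise PERMDISP: ANOVA F on distances to own-group (arithmetic)
    centroids, with permutation of the pooled residual distances."""
    X = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    rng = np.random.default_rng([seed, 509])
    rows = []
    for a, b, na, nb in _pairs(labels):
        za = np.linalg.norm(X[labels == a] - X[labels == a].mean(axis=0), axis=1)
        zb = np.linalg.norm(X[labels == b] - X[labels == b].mean(axis=0), axis=1)
        z = np.concatenate([za, zb])
        u_obs = np.concatenate([np.ones(na), np.zeros(nb)])
        f_obs = _anova_f(z, u_obs)
        U, exact = _two_group_indicators(len(z), na, n_perm, rng)
        f_perm = _anova_f_batch(z, U)
        if exact:
            p = float(np.mean(f_perm >= f_obs - 1e-12))
        else:
            p = _perm_pvalue(f_obs, f_perm)
        rows.append({"label_a": a, "label_b": b, "statistic": f_obs, "p": p,
                     "n_a": na, "n_b": nb, "test": "permdisp"})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = np.maximum(bh_fdr(table["p"].to_numpy()),
                                table["p"].to_numpy())
    return table


def _anova_f(z: np.ndarray, u: np.ndarray) -> float:
    return _anova_f_batch(z, u[None])[0]


def _anova_f_batch(z: np.ndarray, U: np.ndarray) -> np.ndarray:
    """One-way two-group ANOVA F on z for each indicator row of U."""
    n = len(z)
    n1 = U.sum(axis=1)
    n0 = n - n1
    s1 = U @ z
    s0 = z.sum() - s1
    m1 = s1 / n1
    m0 = s0 / n0
    grand = z.mean()
    ss_between = n1 * (m1 - grand) ** 2 + n0 * (m0 - grand) ** 2
    sq = U @ (z ** 2)
    ss1 = sq - n1 * m1 ** 2
    ss0 = (z ** 2).sum() - sq - n0 * m0 ** 2
    ss_within = ss1 + ss0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ss_within > 0, ss_between / 1.0 / (ss_within / (n - 2)), 0.0)
    return f


# ---------------------------------------------------------------------------
# classification / regression

def rf_cv_balanced_accuracy(features: np.ndarray, labels: np.ndarray,
                            n_trees: int = 1000, n_folds: int = 5,
                            seed: int = 0) -> pd.DataFrame:
    """Stratified K-fold random forest with balanced class weights; balanced
    accuracy reported as per-class recall per test fold, averaged over folds."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    rare = uniq[counts < n_folds]
    if rare.size:
        raise ValueError(
            f"label(s) {rare.tolist()} have fewer than {n_folds} members; "
            f"stratified {n_folds}-fold CV is impossible")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    recalls = {l: [] for l in uniq}
    for tr, te in skf.split(X, labels):
        clf = RandomForestClassifier(n_estimators=n_trees,
                                     class_weight="balanced",
                                     random_state=seed, n_jobs=1)
        clf.fit(X[tr], labels[tr])
        pred = clf.predict(X[te])
        for l in uniq:
            mask = labels[te] == l
            if mask.any():
                recalls[l].append(float(np.mean(pred[mask] == l)))
    return pd.DataFrame({"label": list(uniq),
                         "balanced_accuracy": [float(np.mean(recalls[l]))
                                               for l in uniq]})


def ridge_predict_genes(latent: np.ndarray, counts: np.ndarray,
                        gene_names: list[str] | None = None,
                        alpha: float = 1.0, test_fraction: float = 0.2,
                        seed: int = 0) -> pd.DataFrame:
    """Per-gene ridge regression from the latent matrix with an 80/20 split.

    Returns test-set R^2 per gene plus the minimum BH-adjusted univariate
    F-test p-value over latent variables (adjustment over all gene x latent
    tests jointly). Constant responses are flagged with NaN R^2.
    """
    from sklearn.feature_selection import f_regression
    from sklearn.linear_model import Ridge
    from sklearn.metrics import r2_score
    from sklearn.model_selection import train_test_split

    Z = np.asarray(latent, dtype=np.float64)
    Y = np.asarray(counts, dtype=np.float64)
    if Z.shape[0] != Y.shape[0]:
        raise ValueError("latent and counts must have aligned rows")
    n_genes = Y.shape[1]
    names = gene_names or [f"gene_{g}" for g in range(n_genes)]
    # standardized predictors; sklearn Ridge leaves the intercept unpenalised
    sd = Z.std(axis=0)
    Zs = (Z - Z.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    idx_tr, idx_te = train_test_split(np.arange(Z.shape[0]),
                                      test_size=test_fraction,
                                      random_state=seed, shuffle=True)
    r2 = np.full(n_genes, np.nan)
    pmat = np.full((n_genes, Z.shape[1]), np.nan)
    for g in range(n_genes):
        y = Y[:, g]
        if np.std(y[idx_tr]) == 0 or np.std(y) == 0:
            continue
        model = Ridge(alpha=alpha)
        model.fit(Zs[idx_tr], y[idx_tr])
        r2[g] = r2_score(y[idx_te], model.predict(Zs[idx_te]))
        _, pvals = f_regression(Zs, y)
        pmat[g] = pvals
    flat = pmat.ravel()
    ok = np.isfinite(flat)
    q = np.full_like(flat, np.nan)
    if ok.any():
        q[ok] = bh_fdr(flat[ok])
    qr = q.reshape(n_genes, -1)
    qmin = np.array([np.nanmin(row) if np.isfinite(row).any() else np.nan
                     for row in qr])
    return pd.DataFrame({"gene": names, "r2_test": r2, "min_q_f_test": qmin})
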