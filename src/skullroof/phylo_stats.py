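"""Phylogenetically informed statistics for trait tables.

The workhorse is a phylogenetic ANOVA/regression with residual-randomization
permutation (RRPP) inference: the trait and design are GLS-whitened with the
Pagel's-lambda-transformed Brownian covariance, the F statistic of the
whitened fit is referred to a null distribution obtained by permuting the
residuals of the reduced (intercept-only) model, and pairwise least-squares
mean distances between lifestyle classes get permutation p-values with Holm
adjustment.

Also here: Holm step-down adjustment, principal component analysis of the
trait table, and two-block partial least squares (with a convenience wrapper
correlating the phylogeny — as principal coordinates of patristic
distances — with one-hot lifestyle classes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .phylogeny import Tree, fit_lambda_ml, lambda_transform, phylo_vcv

__all__ = [
    "AnovaResult",
    "PcaResult",
    "PlsResult",
    "phylo_anova_rrpp",
    "holm_adjust",
    "pca_traits",
    "two_block_pls",
    "phylo_pls_lifestyle",
]


@dataclass
class AnovaResult:
    lambda_used: float
    F: float
    p: float
    df: tuple[int, int]
    pairwise: pd.DataFrame | None
    n_permutations: int
    seed: int | None
    term: str = "predictor"

    def summary(self) -> str:
        lines = [
            f"Phylogenetic ANOVA (RRPP), term: {self.term}",
            f"  lambda = {self.lambda_used:.4f}",
            f"  F({self.df[0]}, {self.df[1]}) = {self.F:.4f}, "
            f"p = {self.p:.4g} ({self.n_permutations} permutations)",
        ]
        if self.pairwise is not None:
            lines.append(self.pairwise.to_string(index=False))
        return "\n".join(lines)


@dataclass
class PcaResult:
    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_fractions: np.ndarray
    standardized: bool


@dataclass
class PlsResult:
    r_pls: float
    p: float
    singular_values: np.ndarray
    n_permutations: int
    seed: int | None


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def _whiten(V: np.ndarray):
    L = np.linalg.cholesky(V)
    return np.linalg.inv(L)


def _design(predictor, n: int):
    """Cell-means design for a categorical predictor, [1, x] otherwise."""
    pred = np.asarray(predictor)
    if pred.dtype.kind in "OUSb" or isinstance(predictor, pd.Categorical):
        levels = sorted(pd.unique(pred).tolist())
        if len(levels) < 2:
            raise ValueError("categorical predictor needs >= 2 groups")
        counts = pd.Series(pred).value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(f"groups with < 2 members: {small.index.tolist()}")
        X = np.column_stack([(pred == g).astype(float) for g in levels])
        return X, levels, True
    x = pred.astype(float)
    return np.column_stack([np.ones(n), x]), None, False


def phylo_anova_rrpp(
    trait,
    predictor,
    tree: Tree,
    n_perm: int = 10_000,
    seed: int | None = None,
    lam: float | None = None,
    pairwise: bool = True,
) -> AnovaResult:
    """Phylogenetic ANOVA (categorical) or regression (continuous) with RRPP.

    trait and predictor are aligned to the tree tips (dict / Series keyed by
    taxon, or arrays already in tip order).  ``lam`` fixes Pagel's lambda;
    by default it is optimised by ML under the full-model design and clamped
    to [0, 1].
    """
    from .phylogeny import _as_tip_vector

    y = _as_tip_vector(tree, trait)
    if isinstance(predictor, dict):
        pred = np.asarray([predictor[t] for t in tree.tip_labels])
    elif hasattr(predictor, "loc") and hasattr(predictor, "index"):
        pred = np.asarray(predictor.loc[list(tree.tip_labels)])
    else:
        pred = np.asarray(predictor)
    n = tree.n_tips
    X, levels, categorical = _design(pred, n)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")

    if lam is None:
        lam_fit = fit_lambda_ml(tree, y, X=X)
        lam = lam_fit.lam
    V = lambda_transform(phylo_vcv(tree), lam)
    W = _whiten(V)
    yw = W @ y
    Xw = W @ X
    onew = W @ np.ones(n)

    # projections for full and reduced (intercept-only) models
    Qf, _ = np.linalg.qr(Xw)
    Qr, _ = np.linalg.qr(onew[:, None])
    df1 = X.shape[1] - 1 if categorical else X.shape[1] - 1
    df2 = n - X.shape[1]

    def f_stat(Y: np.ndarray) -> np.ndarray:
        # Y: (n,) or (n, B); SSE via orthogonal projections
        fit_f = Qf.T @ Y
        fit_r = Qr.T @ Y
        sst = np.sum(Y * Y, axis=0)
        sse_f = sst - np.sum(fit_f * fit_f, axis=0)
        sse_r = sst - np.sum(fit_r * fit_r, axis=0)
        return ((sse_r - sse_f) / df1) / (sse_f / df2)

    F_obs = float(f_stat(yw))

    rng = np.random.default_rng(seed)
    fit_r = Qr @ (Qr.T @ yw)
    resid_r = yw - fit_r
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Ystar = fit_r[:, None] + resid_r[perms].T  # (n, B)
    F_star = f_stat(Ystar)
    p = (np.sum(F_star >= F_obs - 1e-12) + 1) / (n_perm + 1)

    pw = None
    if categorical and pairwise and levels is not None:
        pinvX = np.linalg.pinv(Xw)
        beta_obs = pinvX @ yw  # GLS group means
        beta_star = pinvX @ Ystar  # (g, B)
        rows = []
        for i, j in combinations(range(len(levels)), 2):
            d_obs = abs(beta_obs[i] - beta_obs[j])
            d_star = np.abs(beta_star[i] - beta_star[j])
            praw = (np.sum(d_star >= d_obs - 1e-12) + 1) / (n_perm + 1)
            rows.append((levels[i], levels[j], d_obs, praw))
        pw = pd.DataFrame(rows, columns=["group_a", "group_b", "distance", "p"])
        pw["p_holm"] = holm_adjust(pw["p"].to_numpy())

    return AnovaResult(
        lambda_used=float(lam), F=F_obs, p=float(p), df=(df1, df2),
        pairwise=pw, n_permutations=n_perm, seed=seed,
        term="lifestyle" if categorical else "covariate",
    )


def pca_traits(trait_table: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """PCA of a complete-case trait table.

    Eigendecomposition of the correlation matrix by default (the traits mix
    units); set standardize=False for the covariance matrix.
    """
    df = trait_table.dropna()
    if df.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    Xc = df.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    if standardize:
        sd = Xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = df.columns[sd == 0].tolist()
            raise ValueError(f"constant columns under standardization: {bad}")
        Xc = Xc / sd
    C = np.cov(Xc, rowvar=False)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    # sign convention: largest-magnitude loading positive
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] *= -1
    scores = Xc @ evecs
    names = [f"PC{i + 1}" for i in range(len(evals))]
    return PcaResult(
        loadings=pd.DataFrame(evecs, index=df.columns, columns=names),
        scores=pd.DataFrame(scores, index=df.index, columns=names),
        variance_fractions=evals / evals.sum(),
        standardized=standardize,
    )


def two_block_pls(X_block, Y_block, n_perm: int = 1000,
                  seed: int | None = None) -> PlsResult:
    """Two-block PLS: SVD of the centred cross-covariance.

    r_pls is the correlation of the first pair of singular scores; the
    permutation p-value shuffles the rows of one block.
    """
    X = np.asarray(X_block, dtype=float)
    Y = np.asarray(Y_block, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("blocks must share row count")
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    def r_first(Yp: np.ndarray) -> tuple[float, np.ndarray]:
        C = Xc.T @ Yp / (n - 1)
        U, sv, Vt = np.linalg.svd(C, full_matrices=False)
        if sv[0] <= 1e-14:
            return 0.0, sv
        u = Xc @ U[:, 0]
        v = Yp @ Vt[0]
        su, svv = u.std(), v.std()
        if su == 0 or svv == 0:
            return 0.0, sv
        return float(abs(np.corrcoef(u, v)[0, 1])), sv

    r_obs, svals = r_first(Yc)
    if svals[0] <= 1e-14:
        warnings.warn("rank-0 cross-covariance: r_pls = 0")
        return PlsResult(0.0, 1.0, svals, n_perm, seed)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        r_p, _ = r_first(Yc[rng.permutation(n)])
        if r_p >= r_obs - 1e-12:
            b += 1
    return PlsResult(r_pls=r_obs, p=(b + 1) / (n_perm + 1),
                     singular_values=svals, n_permutations=n_perm, seed=seed)


def _pcoa(D: np.ndarray, var_cutoff: float = 0.95) -> np.ndarray:
    """Principal coordinates of a distance matrix, retaining axes covering
    var_cutoff of the positive-eigenvalue variance."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(evals.max(), 1.0)
    evals, evecs = evals[pos], evecs[:, pos]
    cum = np.cumsum(evals) / evals.sum()
    k = int(np.searchsorted(cum, var_cutoff) + 1)
    return evecs[:, :k] * np.sqrt(evals[:k])


def phylo_pls_lifestyle(tree: Tree, lifestyle, n_perm: int = 1000,
                        seed: int | None = None,
                        var_cutoff: float = 0.95) -> PlsResult:
    """Phylogeny-vs-lifestyle association via two-block PLS.

    X = principal coordinates of the patristic distance matrix (axes
    retained to var_cutoff of the variance); Y = one-hot lifestyle classes.
    """
    if isinstance(lifestyle, dict):
        states = [lifestyle[t] for t in tree.tip_labels]
    elif hasattr(lifestyle, "loc"):
        states = list(lifestyle.loc[list(tree.tip_labels)])
    else:
        states = list(lifestyle)
    X = _pcoa(tree.patristic(), var_cutoff)
    levels = sorted(set(map(str, states)))
    Y = np.column_stack([[1.0 if str(s) == g else 0.0 for s in states]
                         for g in levels])
    return two_block_pls(X, Y, n_perm=n_perm, seed=seed)
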