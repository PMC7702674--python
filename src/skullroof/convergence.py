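"""Convergence indices C1 and C5 with Brownian-motion simulation nulls.

C1 measures how much of the maximal ancestral divergence between two
putatively convergent lineages has been closed: for a tip pair (i, j),

    C1 = 1 - D_tip / D_max,

where D_tip is the present-day trait distance and D_max the largest
distance between any pair of reconstructed states drawn one from each
lineage (the tips themselves and their ancestors back to and including the
MRCA, with internal states from ML ancestral reconstruction under BM).
Tips are grouped into focal clades (one per independent acquisition of the
fully fossorial lifestyle) and the overall C1 averages the between-clade
tip pairs only.

C5 counts convergence events: the number of lineages entering a region of
trait space defined by the focal-clade phenotypes — a closed interval in
one dimension, a minimum-area enclosing ellipse in two.  Branches are
walked as straight segments between reconstructed endpoint states; a
lineage whose parent end lies outside and whose segment reaches the region
counts one entry, and a root already inside counts as the first entry.

Significance for both indices comes from simulating the trait under the
ML-estimated BM model on the same tree and recomputing the index; the
p-value is (b + 1) / (n_sim + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .phylogeny import (BMParams, Tree, asr_operator, estimate_bm_ml,
                        simulate_bm)

__all__ = [
    "FocalSet",
    "ConvergenceResult",
    "C5Result",
    "c1_univariate",
    "c1_pvalue",
    "c5_univariate",
    "c5_pvalue",
    "c5_bivariate",
    "mean_convergence_vectors",
    "min_enclosing_ellipse",
]


@dataclass
class FocalSet:
    """Focal clades: disjoint tip-label sets, one per convergent clade."""

    clades: list[frozenset[str]]

    def __init__(self, clades) -> None:
        self.clades = [frozenset(c) for c in clades]
        if any(len(c) == 0 for c in self.clades):
            raise ValueError("empty focal clade")
        all_tips = [t for c in self.clades for t in c]
        if len(all_tips) != len(set(all_tips)):
            raise ValueError("focal clades must be mutually disjoint")

    def validate(self, tree: Tree) -> None:
        tips = set(tree.tip_labels)
        bad = [t for c in self.clades for t in c if t not in tips]
        if bad:
            raise KeyError(f"focal taxa not on tree: {bad}")

    @property
    def all_taxa(self) -> list[str]:
        return [t for c in self.clades for t in c]


@dataclass
class ConvergenceResult:
    C1: float
    per_pair: dict[tuple[str, str], float]
    p: float | None = None
    n_sim: int = 0
    seed: int | None = None

    def summary(self) -> str:
        out = f"C1 = {self.C1:.4f} over {len(self.per_pair)} between-clade pairs"
        if self.p is not None:
            out += f"; p = {self.p:.4g} ({self.n_sim} BM simulations)"
        return out


@dataclass
class C5Result:
    C5: int
    region: dict
    entering: list[int]
    p: float | None = None
    n_sim: int = 0
    seed: int | None = None
    fallback_region: bool = False

    def summary(self) -> str:
        out = f"C5 = {self.C5} entering lineages"
        if self.p is not None:
            out += f"; p = {self.p:.4g} ({self.n_sim} BM simulations)"
        return out


# -- C1 -------------------------------------------------------------------


def _ancestor_paths(tree: Tree, focal: FocalSet):
    """For each between-clade tip pair: (tip_i, tip_j, anc_i, anc_j) with
    ancestor node-id lists from the tip back to and including the MRCA."""
    focal.validate(tree)
    pairs = []
    for ca, cb in combinations(focal.clades, 2):
        for a in sorted(ca):
            for b in sorted(cb):
                ia = tree.tip_index([a])[0]
                ib = tree.tip_index([b])[0]
                mrca = tree.mrca(ia, ib)
                pa, pb = [], []
                for u in tree.path_to_root(ia):
                    pa.append(u)
                    if u == mrca:
                        break
                for u in tree.path_to_root(ib):
                    pb.append(u)
                    if u == mrca:
                        break
                pairs.append((a, b, ia, ib, np.array(pa), np.array(pb)))
    return pairs


def _c1_from_values(values: np.ndarray, pairs) -> tuple[float, dict]:
    """values: (n_nodes,) or (n_nodes, B).  Returns overall C1 (scalar or
    length-B array) and per-pair dict for the 1-D case."""
    single = values.ndim == 1
    V = values[:, None] if single else values
    per_pair = {}
    c1s = np.zeros((len(pairs), V.shape[1]))
    for k, (a, b, ia, ib, pa, pb) in enumerate(pairs):
        d_tip = np.abs(V[ia] - V[ib])
        d_max = np.abs(V[pa][:, None, :] - V[pb][None, :, :]).max(axis=(0, 1))
        if np.any(d_max <= 0):
            raise ValueError("D_max = 0: constant trait, C1 undefined")
        c1s[k] = 1.0 - d_tip / d_max
        if single:
            per_pair[(a, b)] = float(c1s[k, 0])
    overall = c1s.mean(axis=0)
    return (float(overall[0]), per_pair) if single else (overall, per_pair)


def _node_values(tree: Tree, trait) -> np.ndarray:
    from .phylogeny import _as_tip_vector

    x = _as_tip_vector(tree, trait)
    w, M = asr_operator(tree)
    mu = float(w @ x)
    out = np.empty(tree.n_nodes)
    out[: tree.n_tips] = x
    out[tree.n_tips :] = mu + M @ (x - mu)
    return out


def c1_univariate(tree: Tree, trait, focal: FocalSet) -> ConvergenceResult:
    """Observed univariate C1 over the between-clade tip pairs."""
    if len(focal.clades) < 2:
        raise ValueError("C1 needs at least 2 focal clades")
    pairs = _ancestor_paths(tree, focal)
    vals = _node_values(tree, trait)
    overall, per_pair = _c1_from_values(vals, pairs)
    return ConvergenceResult(C1=overall, per_pair=per_pair)


def _bm_null_node_values(tree: Tree, trait, n_sim: int, seed) -> np.ndarray:
    """Simulate the BM null (rate/root by ML from the trait) and return
    reconstructed node values, shape (n_nodes, n_sim)."""
    from .phylogeny import _as_tip_vector

    x = _as_tip_vector(tree, trait)
    params = estimate_bm_ml(tree, x)
    tips = simulate_bm(tree, params, n_reps=n_sim, seed=seed)  # (B, n_tips)
    w, M = asr_operator(tree)
    mu = tips @ w  # (B,)
    anc = (tips - mu[:, None]) @ M.T + mu[:, None]
    return np.vstack([tips.T, anc.T])  # (n_nodes, B)


def c1_pvalue(tree: Tree, trait, focal: FocalSet, n_sim: int = 1000,
              seed: int | None = None) -> ConvergenceResult:
    """Observed C1 plus its BM-simulation p-value."""
    if n_sim <= 0:
        raise ValueError("n_sim must be positive")
    res = c1_univariate(tree, trait, focal)
    pairs = _ancestor_paths(tree, focal)
    null_vals = _bm_null_node_values(tree, trait, n_sim, seed)
    c1_null, _ = _c1_from_values(null_vals, pairs)
    b = int(np.sum(c1_null >= res.C1 - 1e-12))
    res.p = (b + 1) / (n_sim + 1)
    res.n_sim = n_sim
    res.seed = seed
    return res


# -- C5 -------------------------------------------------------------------


def _count_entries_interval(tree: Tree, values: np.ndarray, lo, hi) -> np.ndarray:
    """Entering-lineage counts for interval regions.

    values: (n_nodes, B); lo/hi scalars or length-B.  A branch enters when
    its parent end is outside and the straight segment reaches the interval;
    a root inside counts one entry.
    """
    B = values.shape[1]
    lo = np.broadcast_to(np.asarray(lo, dtype=float), (B,))
    hi = np.broadcast_to(np.asarray(hi, dtype=float), (B,))
    inside = (values >= lo) & (values <= hi)
    counts = inside[tree.root].astype(int)
    for u in range(tree.n_nodes):
        p = tree.parent[u]
        if p < 0:
            continue
        a, b = values[p], values[u]
        seg_lo = np.minimum(a, b)
        seg_hi = np.maximum(a, b)
        reaches = (seg_hi >= lo) & (seg_lo <= hi)
        counts += (~inside[p]) & reaches
    return counts


def _entering_branches_interval(tree: Tree, values: np.ndarray, lo: float,
                                hi: float) -> list[int]:
    entering = []
    inside = (values >= lo) & (values <= hi)
    for u in range(tree.n_nodes):
        p = tree.parent[u]
        if p < 0:
            continue
        a, b = values[p], values[u]
        if not inside[p] and max(a, b) >= lo and min(a, b) <= hi:
            entering.append(u)
    return entering


def c5_univariate(tree: Tree, trait, focal: FocalSet) -> C5Result:
    """Number of lineages entering the focal interval [min, max]."""
    focal.validate(tree)
    vals = _node_values(tree, trait)
    idx = tree.tip_index(focal.all_taxa)
    lo, hi = float(vals[idx].min()), float(vals[idx].max())
    count = int(_count_entries_interval(tree, vals[:, None], lo, hi)[0])
    entering = _entering_branches_interval(tree, vals, lo, hi)
    return C5Result(C5=count, region={"type": "interval", "lo": lo, "hi": hi},
                    entering=entering)


def c5_pvalue(tree: Tree, trait, focal: FocalSet, n_sim: int = 1000,
              seed: int | None = None) -> C5Result:
    """Observed univariate C5 plus its BM-simulation p-value.

    The focal region is re-derived from the same focal tips in every
    simulated dataset.
    """
    if n_sim <= 0:
        raise ValueError("n_sim must be positive")
    res = c5_univariate(tree, trait, focal)
    null_vals = _bm_null_node_values(tree, trait, n_sim, seed)
    idx = tree.tip_index(focal.all_taxa)
    lo = null_vals[idx].min(axis=0)
    hi = null_vals[idx].max(axis=0)
    counts = _count_entries_interval(tree, null_vals, lo, hi)
    b = int(np.sum(counts >= res.C5))
    res.p = (b + 1) / (n_sim + 1)
    res.n_sim = n_sim
    res.seed = seed
    return res


# -- bivariate C5 ---------------------------------------------------------


def min_enclosing_ellipse(points: np.ndarray, tol: float = 1e-7,
                          max_iter: int = 2000):
    """Minimum-area enclosing ellipse (Khachiyan's algorithm).

    Returns (centre, E) with the ellipse {x : (x-c)^T E (x-c) <= 1}
    containing every input point.
    """
    P = np.asarray(points, dtype=float)
    n, d = P.shape
    Q = np.column_stack([P, np.ones(n)]).T  # (d+1, n)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = Q @ np.diag(u) @ Q.T
        M = np.einsum("ij,jk,ki->i", Q.T, np.linalg.inv(X), Q)
        j = int(np.argmax(M))
        maximum = M[j]
        step = (maximum - d - 1.0) / ((d + 1.0) * (maximum - 1.0))
        if step <= tol:
            break
        u = (1 - step) * u
        u[j] += step
    c = P.T @ u
    S = (P.T @ np.diag(u) @ P - np.outer(c, c))
    E = np.linalg.inv(S) / d
    # guard against floating-point exclusion of support points
    q = np.einsum("ij,jk,ik->i", P - c, E, P - c)
    E = E / max(q.max(), 1.0)
    return c, E


def _covariance_ellipse(points: np.ndarray, coverage: float = 0.95):
    """Covariance ellipse scaled to contain every focal point."""
    from scipy.stats import chi2

    P = np.asarray(points, dtype=float)
    c = P.mean(axis=0)
    S = np.cov(P, rowvar=False)
    E = np.linalg.inv(S * chi2.ppf(coverage, df=2))
    q = np.einsum("ij,jk,ik->i", P - c, E, P - c)
    return c, E / max(q.max(), 1.0)


def _padded_bounding_ellipse(points: np.ndarray, pad: float = 0.05):
    P = np.asarray(points, dtype=float)
    c = 0.5 * (P.max(axis=0) + P.min(axis=0))
    half = 0.5 * np.ptp(P, axis=0)
    scale = np.maximum(half * (1 + pad), 1e-9 + pad * max(np.abs(P).max(), 1.0))
    E = np.diag(1.0 / scale**2) / 2.0
    q = np.einsum("ij,jk,ik->i", P - c, E, P - c)
    return c, E / max(q.max(), 1.0)


def _segment_reaches_ellipse(a, b, c, E) -> bool:
    """Does the straight segment a->b intersect {(x-c)^T E (x-c) <= 1}?"""
    d = b - a
    f = a - c
    A = d @ E @ d
    Bq = 2.0 * (f @ E @ d)
    C = f @ E @ f - 1.0
    if C <= 0:
        return True  # a inside
    if A <= 1e-30:
        return False
    t = np.clip(-Bq / (2 * A), 0.0, 1.0)
    val = A * t * t + Bq * t + C
    return bool(val <= 0)


def c5_bivariate(tree: Tree, trait_pair, focal: FocalSet,
                 region: str = "min_area") -> C5Result:
    """Lineages entering the 2-D focal morphospace ellipse.

    trait_pair: two tip-value mappings (or an (n_tips, 2) array in tip
    order).  region: 'min_area' (Khachiyan, default) or 'covariance'
    (95% covariance ellipse inflated to contain all focal tips).  Fewer
    than 3 non-collinear focal points fall back to a padded bounding
    ellipse, flagged on the result.
    """
    focal.validate(tree)
    from .phylogeny import _as_tip_vector

    if isinstance(trait_pair, (list, tuple)):
        cols = [_as_tip_vector(tree, t) for t in trait_pair]
        tips = np.column_stack(cols)
    else:
        tips = np.asarray(trait_pair, dtype=float)
    if tips.shape != (tree.n_tips, 2):
        raise ValueError("trait_pair must give two traits per tip")
    nodes = np.column_stack([_node_values(tree, tips[:, j]) for j in range(2)])
    idx = tree.tip_index(focal.all_taxa)
    pts = nodes[idx]
    fallback = False
    spread = np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9)
    if len(pts) < 3 or spread < 2:
        c, E = _padded_bounding_ellipse(pts)
        fallback = True
    elif region == "covariance":
        c, E = _covariance_ellipse(pts)
    else:
        c, E = min_enclosing_ellipse(pts)
    q = np.einsum("ij,jk,ik->i", nodes - c, E, nodes - c)
    inside = q <= 1.0 + 1e-9
    count = int(inside[tree.root])
    entering: list[int] = []
    for u in range(tree.n_nodes):
        p = tree.parent[u]
        if p < 0:
            continue
        if not inside[p] and _segment_reaches_ellipse(nodes[p], nodes[u], c, E):
            entering.append(u)
            count += 1
    return C5Result(
        C5=count,
        region={"type": "ellipse", "centre": c.tolist(),
                "shape": E.tolist(), "kind": region},
        entering=entering, fallback_region=fallback,
    )


def mean_convergence_vectors(tree: Tree, node_values: np.ndarray,
                             entering: list[int]) -> np.ndarray:
    """Component-wise mean of (child - parent) vectors of entering lineages."""
    if len(entering) == 0:
        raise ValueError("no entering lineages")
    vals = np.atleast_2d(np.asarray(node_values, dtype=float).T).T
    vecs = np.array([vals[u] - vals[tree.parent[u]] for u in entering])
    return vecs.mean(axis=0)
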