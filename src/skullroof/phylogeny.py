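"""Rooted-tree handling and phylogenetic machinery.

This module provides the tree container used throughout the package and the
comparative-methods primitives built on it: the Brownian-motion (BM)
covariance structure, Pagel's lambda signal estimation, maximum-likelihood
ancestral states for continuous traits, Mk models for discrete characters,
stochastic character mapping (simmap) with uniformized branch histories, and
parsimony-based clustering summaries (Fitch steps, Retention Index).

Trees are stored as flat arrays (parent pointers, branch lengths, traversal
orders) for fast vectorised computation; Newick text is parsed with dendropy
and converted on the way in and out.  Tips occupy node ids ``0..n_tips-1``
in the order of ``tip_labels``; internal nodes follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import cho_factor, cho_solve, expm
from scipy.optimize import minimize, minimize_scalar

__all__ = [
    "Tree",
    "BMParams",
    "LambdaFit",
    "MkModel",
    "SimmapHistory",
    "parse_newick",
    "write_newick",
    "prune_tree",
    "phylo_vcv",
    "lambda_transform",
    "fit_lambda_ml",
    "simulate_bm",
    "asr_continuous",
    "fit_mk",
    "mk_loglik",
    "simmap_sample",
    "branch_posterior",
    "fitch_steps",
    "retention_index",
]


class NewickError(ValueError):
    pass


@dataclass
class Tree:
    """Rooted phylogeny with branch lengths in time units.

    parent[i] is the parent node id of node i (-1 for the root);
    blen[i] is the length of the branch subtending node i (0 for the root).
    Tips are ids 0..n_tips-1, labelled by tip_labels in that order.
    """

    parent: np.ndarray
    blen: np.ndarray
    tip_labels: list[str]
    children: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.blen = np.asarray(self.blen, dtype=float)
        if np.any(self.blen < 0):
            raise ValueError("negative branch length")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise NewickError("duplicate tip labels")
        n = len(self.parent)
        if not self.children:
            self.children = [[] for _ in range(n)]
            for i in range(n):
                if self.parent[i] >= 0:
                    self.children[self.parent[i]].append(i)
        roots = [i for i in range(n) if self.parent[i] < 0]
        if len(roots) != 1:
            raise ValueError(f"tree must have a single root, found {len(roots)}")
        self.root = roots[0]
        self._postorder: np.ndarray | None = None
        self._preorder: np.ndarray | None = None
        self._depths: np.ndarray | None = None

    # -- basic accessors -------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def postorder(self) -> np.ndarray:
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            while stack:
                u = stack.pop()
                order.append(u)
                stack.extend(self.children[u])
            self._preorder = np.array(order, dtype=int)
            self._postorder = self._preorder[::-1].copy()
        return self._postorder

    @property
    def preorder(self) -> np.ndarray:
        self.postorder
        return self._preorder  # type: ignore[return-value]

    @property
    def node_depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            for u in self.preorder:
                if self.parent[u] >= 0:
                    d[u] = d[self.parent[u]] + self.blen[u]
            self._depths = d
        return self._depths

    def tip_index(self, labels) -> np.ndarray:
        lut = {lab: i for i, lab in enumerate(self.tip_labels)}
        missing = [x for x in labels if x not in lut]
        if missing:
            raise KeyError(f"taxa not on tree: {missing}")
        return np.array([lut[x] for x in labels], dtype=int)

    def path_to_root(self, node: int) -> list[int]:
        out = [node]
        while self.parent[out[-1]] >= 0:
            out.append(int(self.parent[out[-1]]))
        return out

    def mrca(self, a: int, b: int) -> int:
        anc_a = set(self.path_to_root(a))
        for u in self.path_to_root(b):
            if u in anc_a:
                return u
        raise RuntimeError("disconnected tree")

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        d = self.node_depths[: self.n_tips]
        return bool(np.ptp(d) <= tol * max(1.0, d.max()))

    def total_length(self) -> float:
        return float(self.blen.sum())

    def patristic(self) -> np.ndarray:
        V = phylo_vcv(self)
        dg = np.diag(V)
        return dg[:, None] + dg[None, :] - 2 * V

    def node_path_matrix(self) -> np.ndarray:
        """Shared root-to-MRCA path length between every pair of nodes."""
        n = self.n_nodes
        # U[u, e] = 1 if edge subtending node e lies on the root->u path
        U = np.zeros((n, n))
        for u in self.preorder:
            p = self.parent[u]
            if p >= 0:
                U[u] = U[p]
                U[u, u] = 1.0
        return (U * self.blen) @ U.T


# -- Newick I/O ----------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> Tree:
    nodes = list(dtree.preorder_node_iter())
    tips = [nd for nd in nodes if nd.is_leaf()]
    labels = [nd.taxon.label if nd.taxon else (nd.label or "") for nd in tips]
    if any(lab == "" for lab in labels):
        raise NewickError("unlabelled tip")
    if len(set(labels)) != len(labels):
        raise NewickError("duplicate tip labels")
    internals = [nd for nd in nodes if not nd.is_leaf()]
    idx = {id(nd): i for i, nd in enumerate(tips)}
    idx.update({id(nd): len(tips) + j for j, nd in enumerate(internals)})
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    blen = np.zeros(n)
    for nd in nodes:
        i = idx[id(nd)]
        if nd.parent_node is not None:
            parent[i] = idx[id(nd.parent_node)]
            blen[i] = float(nd.edge.length or 0.0)
    return Tree(parent=parent, blen=blen, tip_labels=labels)


def parse_newick(text: str) -> Tree:
    """Parse a Newick string (quoted labels supported) into a Tree."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"newick parse error: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: Tree, precision: int = 12) -> str:
    def render(u: int) -> str:
        if u < tree.n_tips:
            lab = tree.tip_labels[u]
            if any(ch in lab for ch in " ()[]:;,'"):
                lab = "'" + lab.replace("'", "''") + "'"
            core = lab
        else:
            core = "(" + ",".join(render(c) for c in tree.children[u]) + ")"
        if tree.parent[u] >= 0:
            core += f":{tree.blen[u]:.{precision}g}"
        return core

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * tree.n_nodes + 100))
    try:
        return render(tree.root) + ";"
    finally:
        sys.setrecursionlimit(old)


def read_newick(path) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def prune_tree(tree: Tree, keep_taxa) -> Tree:
    """Restrict the tree to keep_taxa, suppressing unary nodes.

    Patristic distances among the kept tips are preserved exactly: the
    lengths of fused branches are summed.
    """
    keep = list(keep_taxa)
    unknown = [t for t in keep if t not in set(tree.tip_labels)]
    if unknown:
        raise KeyError(f"taxa not on tree: {unknown}")
    if len(set(keep)) != len(keep):
        raise ValueError("duplicate taxa in keep list")
    keep_ids = set(tree.tip_index(keep).tolist())
    # number of kept tips below each node
    n_below = np.zeros(tree.n_nodes, dtype=int)
    for u in tree.postorder:
        if u < tree.n_tips:
            n_below[u] = 1 if u in keep_ids else 0
        else:
            n_below[u] = sum(n_below[c] for c in tree.children[u])
    # new root: deepest node with all kept tips below
    new_root = tree.root
    total = n_below[tree.root]
    while True:
        nxt = [c for c in tree.children[new_root] if n_below[c] == total]
        if nxt and n_below[new_root] == total:
            cand = nxt[0]
            if n_below[cand] == total:
                new_root = cand
                continue
        break

    new_parent: list[int] = []
    new_blen: list[float] = []
    new_labels: list[str] = []

    def build(u: int, parent_new: int, carried: float) -> None:
        kids = [c for c in tree.children[u] if n_below[c] > 0]
        if u < tree.n_tips:
            new_parent.append(parent_new)
            new_blen.append(carried)
            new_labels.append(tree.tip_labels[u])
            return
        if len(kids) == 1:
            # unary node: fuse branch into child
            build(kids[0], parent_new, carried + tree.blen[kids[0]])
            return
        new_parent.append(parent_new)
        new_blen.append(carried)
        my_id = len(new_parent) - 1
        for c in kids:
            build(c, my_id, tree.blen[c])

    # descend while the new root would be unary (its branch is dropped)
    while new_root >= tree.n_tips and \
            len([c for c in tree.children[new_root] if n_below[c] > 0]) == 1:
        new_root = [c for c in tree.children[new_root] if n_below[c] > 0][0]
    build(new_root, -1, 0.0)
    # reorder: tips first (in DFS encounter order), then internals
    n_new = len(new_parent)
    tip_set = set(range(n_new)) - set(p for p in new_parent if p >= 0)
    order = [i for i in range(n_new) if i in tip_set] + \
        [i for i in range(n_new) if i not in tip_set]
    remap = {old: new for new, old in enumerate(order)}
    parent_arr = np.full(n_new, -1, dtype=int)
    blen_arr = np.zeros(n_new)
    labels_arr = [""] * len(tip_set)
    lab_iter = iter(new_labels)
    for i in range(n_new):
        j = remap[i]
        parent_arr[j] = remap[new_parent[i]] if new_parent[i] >= 0 else -1
        blen_arr[j] = new_blen[i]
        if i in tip_set:
            labels_arr[j] = next(lab_iter)
    return Tree(parent=parent_arr, blen=blen_arr, tip_labels=labels_arr)


# -- BM covariance and Pagel's lambda -----------------------------------


def phylo_vcv(tree: Tree) -> np.ndarray:
    """Brownian-motion tip covariance: shared root-to-MRCA path lengths."""
    return tree.node_path_matrix()[: tree.n_tips, : tree.n_tips]


def lambda_transform(vcv: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal covariances by lambda, keeping the diagonal.

    The matrix form is exact for non-ultrametric trees (fossil tips), unlike
    internal-branch rescaling.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]; clamp upstream")
    out = lam * np.asarray(vcv, dtype=float)
    np.fill_diagonal(out, np.diag(vcv))
    return out


@dataclass
class BMParams:
    sigma2: float
    root_state: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


@dataclass
class LambdaFit:
    lam: float
    logL: float
    clamped: bool
    sigma2: float
    coef: np.ndarray

    def summary(self) -> str:
        return (
            f"Pagel's lambda ML fit: lambda={self.lam:.4f}"
            f"{' (clamped)' if self.clamped else ''}, logL={self.logL:.3f}, "
            f"sigma2={self.sigma2:.5g}"
        )


def _gls_profile_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Profile (over beta, sigma2) multivariate-normal log-likelihood."""
    n = len(y)
    c, low = cho_factor(V, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    Xi = cho_solve((c, low), X)
    yi = cho_solve((c, low), y)
    XtVX = X.T @ Xi
    beta = np.linalg.solve(XtVX, X.T @ yi)
    r = y - X @ beta
    ri = cho_solve((c, low), r)
    s2 = float(r @ ri) / n
    if s2 <= 0:
        raise ValueError("zero residual variance: lambda undefined")
    ll = -0.5 * (n * math.log(2 * math.pi * s2) + logdet + n)
    return ll, beta, s2


def fit_lambda_ml(tree: Tree, trait, X: np.ndarray | None = None) -> LambdaFit:
    """ML estimate of Pagel's lambda for trait ~ X (default intercept).

    The likelihood is the GLS multivariate normal under the
    lambda-transformed BM covariance, maximised over lambda in [0, 1]; an
    optimum pinned at either bound is reported as clamped.
    """
    y = _as_tip_vector(tree, trait)
    n = tree.n_tips
    if n < 4:
        raise ValueError("need at least 4 tips")
    if np.ptp(y) == 0:
        raise ValueError("zero trait variance: lambda undefined")
    if X is None:
        X = np.ones((n, 1))
    V = phylo_vcv(tree)
    d = np.diag(V)
    ultra = np.ptp(d) <= 1e-10 * max(1.0, d.max())
    if ultra:
        # V(lam) = lam*V + (1-lam)*d*I shares V's eigenvectors: O(n) per eval
        w, U = np.linalg.eigh(V)
        yr = U.T @ y
        Xr = U.T @ X
        d0 = d[0]

        def negll(lam: float) -> float:
            ev = lam * w + (1 - lam) * d0
            if ev.min() <= 0:
                return np.inf
            Xw = Xr / ev[:, None]
            beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
            r = yr - Xr @ beta
            s2 = float(r @ (r / ev)) / n
            if s2 <= 0:
                return np.inf
            return 0.5 * (n * math.log(2 * math.pi * s2) + np.log(ev).sum() + n)

    else:

        def negll(lam: float) -> float:
            try:
                ll, _, _ = _gls_profile_loglik(y, X, lambda_transform(V, lam))
            except np.linalg.LinAlgError:
                return np.inf
            return -ll

    res = minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(res.x)
    # the bounded optimiser never returns the exact bounds; snap if better
    for b in (0.0, 1.0):
        if negll(b) <= res.fun + 1e-10:
            lam = b
    ll, beta, s2 = _gls_profile_loglik(y, X, lambda_transform(V, lam))
    return LambdaFit(lam=lam, logL=ll, clamped=lam in (0.0, 1.0), sigma2=s2,
                     coef=beta)


def _as_tip_vector(tree: Tree, trait) -> np.ndarray:
    """Accept dict/Series/array of tip values, return array in tip order."""
    if isinstance(trait, dict):
        return np.array([float(trait[t]) for t in tree.tip_labels])
    if hasattr(trait, "loc") and hasattr(trait, "index"):
        return np.asarray(trait.loc[list(tree.tip_labels)], dtype=float)
    arr = np.asarray(trait, dtype=float)
    if arr.shape[0] != tree.n_tips:
        raise ValueError("trait length does not match tip count")
    return arr


def estimate_bm_ml(tree: Tree, trait, reml: bool = False) -> BMParams:
    """ML (or REML) estimate of the BM rate and root state from tip values."""
    y = _as_tip_vector(tree, trait)
    V = phylo_vcv(tree)
    c, low = cho_factor(V, lower=True)
    one = np.ones(len(y))
    Vi1 = cho_solve((c, low), one)
    mu = float(one @ cho_solve((c, low), y)) / float(one @ Vi1)
    r = y - mu
    s2 = float(r @ cho_solve((c, low), r)) / (len(y) - (1 if reml else 0))
    return BMParams(sigma2=max(s2, 1e-12), root_state=mu)


def simulate_bm(
    tree: Tree,
    params: BMParams,
    n_reps: int = 1,
    seed: int | np.random.Generator | None = None,
    return_nodes: bool = False,
) -> np.ndarray:
    """Simulate Brownian motion down the tree.

    Returns an (n_reps, n_tips) array, or (n_reps, n_nodes) when
    return_nodes is set (tips occupy the leading columns).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = tree.n_nodes
    steps = rng.standard_normal((n_reps, n)) * np.sqrt(params.sigma2 * tree.blen)
    vals = np.empty((n_reps, n))
    for u in tree.preorder:
        p = tree.parent[u]
        if p < 0:
            vals[:, u] = params.root_state
        else:
            vals[:, u] = vals[:, p] + steps[:, u]
    return vals if return_nodes else vals[:, : tree.n_tips]


# -- continuous ancestral states -----------------------------------------


def asr_operator(tree: Tree):
    """Linear operator for BM/GLS ancestral states.

    Returns (w, M) with w the GLS root-mean weights over tips and M the
    matrix such that node estimates = mu + M @ (x - mu) for internal nodes
    (ordered n_tips..n_nodes-1).  The estimates are the conditional means of
    a multivariate normal and coincide with the ML states under BM.
    """
    full = tree.node_path_matrix()
    Vtt = full[: tree.n_tips, : tree.n_tips]
    Vnt = full[tree.n_tips :, : tree.n_tips]
    c, low = cho_factor(Vtt, lower=True)
    one = np.ones(tree.n_tips)
    Vi1 = cho_solve((c, low), one)
    w = Vi1 / float(one @ Vi1)
    M = Vnt @ cho_solve((c, low), np.eye(tree.n_tips))
    return w, M


def asr_continuous(tree: Tree, tip_values) -> np.ndarray:
    """ML ancestral states under BM for all nodes (length n_nodes).

    Tip entries hold the observed values; the root estimate equals the GLS
    mean of the tips under the BM covariance.
    """
    x = _as_tip_vector(tree, tip_values)
    if np.any(~np.isfinite(x)):
        raise ValueError("all tips must have finite values")
    w, M = asr_operator(tree)
    mu = float(w @ x)
    out = np.empty(tree.n_nodes)
    out[: tree.n_tips] = x
    out[tree.n_tips :] = mu + M @ (x - mu)
    return out


def interpolate_branch_states(tree: Tree, node_values: np.ndarray, n_grid: int = 20):
    """contMap-style linear interpolation of a continuous trait along branches.

    Returns {child_id: (positions_from_parent, values)} for every non-root
    node, with n_grid points per branch.
    """
    out = {}
    frac = (np.arange(n_grid) + 0.5) / n_grid
    for u in range(tree.n_nodes):
        p = tree.parent[u]
        if p < 0:
            continue
        t = tree.blen[u] * frac
        vals = node_values[p] + (node_values[u] - node_values[p]) * frac
        out[int(u)] = (t, vals)
    return out


# -- Mk models and stochastic character mapping ---------------------------


@dataclass
class MkModel:
    states: list[str]
    Q: np.ndarray
    flavour: str = "ER"
    logL: float = float("nan")

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        k = len(self.states)
        if self.Q.shape != (k, k):
            raise ValueError("Q shape mismatch")
        off = self.Q[~np.eye(k, dtype=bool)]
        if np.any(off < -1e-12):
            raise ValueError("negative off-diagonal rate")
        if np.any(np.abs(self.Q.sum(axis=1)) > 1e-8 * max(1.0, np.abs(self.Q).max())):
            raise ValueError("Q rows must sum to zero")

    @property
    def k(self) -> int:
        return len(self.states)

    def stationary(self) -> np.ndarray:
        k = self.k
        A = np.vstack([self.Q.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0, None)
        s = pi.sum()
        return pi / s if s > 0 else np.full(k, 1.0 / k)

    def summary(self) -> str:
        return (f"Mk ({self.flavour}) over states {self.states}; "
                f"rates {np.round(self.Q, 5).tolist()}; logL={self.logL:.3f}")


def _tip_state_matrix(tree: Tree, tip_states, states: list[str]) -> np.ndarray:
    sidx = {s: i for i, s in enumerate(states)}
    L = np.zeros((tree.n_tips, len(states)))
    if isinstance(tip_states, dict):
        seq = [tip_states[t] for t in tree.tip_labels]
    elif hasattr(tip_states, "loc"):
        seq = list(tip_states.loc[list(tree.tip_labels)])
    else:
        seq = list(tip_states)
    for i, s in enumerate(seq):
        L[i, sidx[str(s)]] = 1.0
    return L


def _branch_pmats(tree: Tree, Q: np.ndarray) -> dict[float, np.ndarray]:
    return {float(t): expm(Q * t) for t in np.unique(tree.blen)}


def _pruning_partials(tree: Tree, Q: np.ndarray, tipL: np.ndarray) -> np.ndarray:
    """Conditional likelihoods D[u, s] = P(tip data below u | state(u)=s)."""
    k = Q.shape[0]
    P = _branch_pmats(tree, Q)
    D = np.ones((tree.n_nodes, k))
    D[: tree.n_tips] = tipL
    for u in tree.postorder:
        if u < tree.n_tips:
            continue
        acc = np.ones(k)
        for c in tree.children[u]:
            acc = acc * (P[float(tree.blen[c])] @ D[c])
        D[u] = acc
    return D


def mk_loglik(tree: Tree, tip_states, model: MkModel, root_prior="stationary") -> float:
    tipL = _tip_state_matrix(tree, tip_states, model.states)
    D = _pruning_partials(tree, model.Q, tipL)
    pi = model.stationary() if root_prior == "stationary" else np.full(model.k, 1 / model.k)
    lik = float(pi @ D[tree.root])
    if lik <= 0:
        return -np.inf
    return math.log(lik)


def fit_mk(tree: Tree, tip_states, flavour: str = "ER",
           root_prior: str = "stationary") -> MkModel:
    """ML Mk transition model via Felsenstein pruning.

    ER fits a single exchange rate; ARD one rate per ordered state pair.
    An invariant character drives the rate to the lower search bound.
    """
    if isinstance(tip_states, dict):
        obs = [str(tip_states[t]) for t in tree.tip_labels]
    elif hasattr(tip_states, "loc"):
        obs = [str(x) for x in tip_states.loc[list(tree.tip_labels)]]
    else:
        obs = [str(x) for x in tip_states]
    states = sorted(set(obs))
    k = len(states)
    if k < 2:
        raise ValueError("need at least 2 observed states")
    tipL = _tip_state_matrix(tree, dict(zip(tree.tip_labels, obs)), states)
    pi_mode = root_prior

    def build_Q(logr: np.ndarray) -> np.ndarray:
        r = np.exp(logr)
        Q = np.zeros((k, k))
        if flavour == "ER":
            Q[:] = r[0]
        else:
            idx = 0
            for i in range(k):
                for j in range(k):
                    if i != j:
                        Q[i, j] = r[idx]
                        idx += 1
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def negll(logr: np.ndarray) -> float:
        Q = build_Q(np.clip(logr, -20, 8))
        D = _pruning_partials(tree, Q, tipL)
        if pi_mode == "stationary":
            pi = MkModel(states, Q).stationary()
        else:
            pi = np.full(k, 1.0 / k)
        lik = float(pi @ D[tree.root])
        return -math.log(lik) if lik > 0 else np.inf

    n_par = 1 if flavour == "ER" else k * (k - 1)
    x0 = np.full(n_par, math.log(max(len(states) / max(tree.total_length(), 1e-9), 1e-6)))
    res = minimize(negll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
    Q = build_Q(np.clip(res.x, -20, 8))
    return MkModel(states=states, Q=Q, flavour=flavour, logL=-float(res.fun))


@dataclass
class SimmapHistory:
    """One sampled character history: per-branch (state, duration) segments.

    segments maps the child node id of each branch to an ordered list from
    the parent end to the child end; durations sum to the branch length.
    node_states holds the sampled state at every node.
    """

    states: list[str]
    segments: dict[int, list[tuple[str, float]]]
    node_states: dict[int, str]

    def n_changes(self) -> int:
        return sum(len(seg) - 1 for seg in self.segments.values())

    def state_at(self, child: int, t_from_parent: float) -> str:
        acc = 0.0
        segs = self.segments[child]
        for s, d in segs:
            acc += d
            if t_from_parent <= acc + 1e-12:
                return s
        return segs[-1][0]

    def to_newick(self, tree: Tree) -> str:
        """SIMMAP-annotated Newick: branch annotations {state,time:...}."""

        def render(u: int) -> str:
            if u < tree.n_tips:
                core = tree.tip_labels[u]
            else:
                core = "(" + ",".join(render(c) for c in tree.children[u]) + ")"
            if tree.parent[u] >= 0:
                ann = ":".join(f"{s},{d:.9g}" for s, d in self.segments[u])
                core += ":{" + ann + "}"
            return core

        return render(tree.root) + ";"


def _sample_path_uniformized(Q, a, b, t, rng, Pt_ab, cap_factor=50):
    """States/durations on a branch of length t conditioned on endpoints a->b.

    Uniformization: jumps of the subordinating Poisson process at rate
    omega = max diagonal rate; the self-transition-padded chain R = I + Q/omega.
    """
    k = Q.shape[0]
    omega = float(np.max(-np.diag(Q)))
    if omega <= 0 or t <= 0:
        if a != b:
            raise RuntimeError("impossible endpoint pair on zero-rate branch")
        return [(a, t)]
    R = np.eye(k) + Q / omega
    # P(N = n | a, b) proportional to Poisson(omega t; n) * (R^n)[a, b]
    lam = omega * t
    cap = int(max(10, lam + 10 * math.sqrt(lam) + 10, cap_factor))
    Rp = [np.linalg.matrix_power(R, n) for n in range(cap + 1)]
    log_pois = -lam + np.arange(cap + 1) * math.log(lam) - \
        np.array([math.lgamma(n + 1) for n in range(cap + 1)])
    wts = np.exp(log_pois) * np.array([Rp[n][a, b] for n in range(cap + 1)])
    total = wts.sum()
    if total <= 0:
        raise RuntimeError("endpoint pair has zero probability")
    n = int(rng.choice(cap + 1, p=wts / total))
    # sample the embedded state sequence conditioned on endpoints
    seq = [a]
    for i in range(1, n):
        prev = seq[-1]
        probs = R[prev] * Rp[n - i][:, b]
        probs = probs / probs.sum()
        seq.append(int(rng.choice(k, p=probs)))
    if n >= 1:
        seq.append(b)
    times = np.sort(rng.uniform(0, t, size=n))
    # collapse virtual (self) jumps into segments
    segs: list[tuple[int, float]] = []
    cur, t0 = a, 0.0
    for s, tj in zip(seq[1:], times):
        if s != cur:
            segs.append((cur, tj - t0))
            cur, t0 = s, tj
    segs.append((cur, t - t0))
    return segs


def simmap_sample(
    tree: Tree,
    tip_states,
    model: MkModel,
    n_maps: int = 100,
    seed: int | np.random.Generator | None = None,
    root_prior: str = "stationary",
) -> list[SimmapHistory]:
    """Stochastic character maps conditioned on tip states and an Mk model.

    Joint node states are drawn by pruning + stochastic traceback; branch
    histories conditioned on the endpoints are drawn by uniformization, so
    segment durations sum to branch lengths exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = model.k
    Q = model.Q
    tipL = _tip_state_matrix(tree, tip_states, model.states)
    D = _pruning_partials(tree, Q, tipL)
    P = _branch_pmats(tree, Q)
    pi = model.stationary() if root_prior == "stationary" else np.full(k, 1.0 / k)

    # uniformization caches shared across maps and branches
    omega = float(np.max(-np.diag(Q)))
    if omega > 0:
        R = np.eye(k) + Q / omega
        Rpow = [np.eye(k)]

        def rpow(n: int) -> np.ndarray:
            while len(Rpow) <= n:
                Rpow.append(Rpow[-1] @ R)
            return Rpow[n]

        # per unique branch length: jump-count weight table (cap+1, k, k)
        jump_tbl: dict[float, np.ndarray] = {}

        def jump_weights(t: float) -> np.ndarray:
            if t not in jump_tbl:
                lam = omega * t
                cap = int(max(10, lam + 10 * math.sqrt(lam) + 10))
                lp = -lam + np.arange(cap + 1) * math.log(lam) - \
                    np.array([math.lgamma(n + 1) for n in range(cap + 1)])
                stack = np.stack([rpow(n) for n in range(cap + 1)])
                jump_tbl[t] = np.exp(lp)[:, None, None] * stack
            return jump_tbl[t]

    def sample_branch(a: int, b: int, t: float) -> list[tuple[int, float]]:
        if omega <= 0 or t <= 0:
            if a != b:
                raise RuntimeError("impossible endpoints on zero-rate branch")
            return [(a, t)]
        wts = jump_weights(t)[:, a, b]
        total = wts.sum()
        if total <= 0:
            raise RuntimeError("endpoint pair has zero probability")
        n = int(np.searchsorted(np.cumsum(wts), rng.uniform(0, total)))
        seq = [a]
        for i in range(1, n):
            probs = R[seq[-1]] * rpow(n - i)[:, b]
            probs = probs / probs.sum()
            seq.append(int(np.searchsorted(np.cumsum(probs), rng.uniform())))
        if n >= 1:
            seq.append(b)
        times = np.sort(rng.uniform(0, t, size=n))
        segs: list[tuple[int, float]] = []
        cur, t0 = a, 0.0
        for s, tj in zip(seq[1:], times):
            if s != cur:
                segs.append((cur, tj - t0))
                cur, t0 = s, tj
        segs.append((cur, t - t0))
        return segs

    maps: list[SimmapHistory] = []
    ks = np.arange(k)
    for _ in range(n_maps):
        node_state: dict[int, int] = {}
        pr = pi * D[tree.root]
        pr = pr / pr.sum()
        node_state[tree.root] = int(np.searchsorted(np.cumsum(pr), rng.uniform()))
        for u in tree.preorder:
            if u == tree.root:
                continue
            ps = node_state[tree.parent[u]]
            probs = P[float(tree.blen[u])][ps] * D[u]
            probs = probs / probs.sum()
            node_state[u] = int(np.searchsorted(np.cumsum(probs), rng.uniform()))
        segments: dict[int, list[tuple[str, float]]] = {}
        for u in range(tree.n_nodes):
            if tree.parent[u] < 0:
                continue
            segs = sample_branch(node_state[tree.parent[u]], node_state[u],
                                 float(tree.blen[u]))
            segments[u] = [(model.states[s], d) for s, d in segs]
        maps.append(SimmapHistory(
            states=list(model.states),
            segments=segments,
            node_states={u: model.states[s] for u, s in node_state.items()},
        ))
    return maps


def branch_posterior(
    tree: Tree,
    histories: list[SimmapHistory],
    focal_state: str,
    n_grid: int = 20,
    threshold: float = 0.5,
):
    """Posterior profile of the focal state along every branch.

    Returns (profiles, acquisitions): profiles maps child node id to an
    n_grid array of the fraction of maps in the focal state at evenly spaced
    points from the parent end; acquisitions lists branches on which the
    posterior rises through the threshold (parent-end at or below it,
    child-end above), the >50% rule used to call independent origins.
    """
    if not histories:
        raise ValueError("need at least one history")
    profiles: dict[int, np.ndarray] = {}
    frac = (np.arange(n_grid) + 0.5) / n_grid
    for u in range(tree.n_nodes):
        if tree.parent[u] < 0:
            continue
        t = tree.blen[u] * frac
        counts = np.zeros(n_grid)
        for h in histories:
            counts += [h.state_at(u, ti) == focal_state for ti in t]
        profiles[u] = counts / len(histories)
    node_post = {u: np.mean([h.node_states[u] == focal_state for h in histories])
                 for u in range(tree.n_nodes)}
    acquisitions = []
    for u, prof in profiles.items():
        p_parent = node_post[int(tree.parent[u])]
        p_child = node_post[u]
        if p_parent <= threshold < p_child:
            acquisitions.append(int(u))
    return profiles, acquisitions


# -- parsimony ------------------------------------------------------------


def fitch_steps(tree: Tree, character) -> int:
    """Minimum parsimony steps (Hartigan's generalisation for polytomies)."""
    if isinstance(character, dict):
        obs = [str(character[t]) for t in tree.tip_labels]
    elif hasattr(character, "loc"):
        obs = [str(x) for x in character.loc[list(tree.tip_labels)]]
    else:
        obs = [str(x) for x in character]
    states = sorted(set(obs))
    sidx = {s: i for i, s in enumerate(states)}
    sets: dict[int, frozenset[int]] = {}
    steps = 0
    for u in tree.postorder:
        if u < tree.n_tips:
            sets[u] = frozenset({sidx[obs[u]]})
            continue
        counts = np.zeros(len(states), dtype=int)
        for c in tree.children[u]:
            for s in sets[c]:
                counts[s] += 1
        K = counts.max()
        sets[u] = frozenset(np.flatnonzero(counts == K).tolist())
        steps += len(tree.children[u]) - K
    return steps


def retention_index(tree: Tree, character) -> float:
    """Retention Index: (g - s) / (g - m).

    s = parsimony steps on the tree, m = k - 1 (the minimum on any tree),
    g = n_tips - max state frequency (the maximum on any tree).  Undefined
    for an invariant character (g = m = 0).
    """
    if isinstance(character, dict):
        obs = [str(character[t]) for t in tree.tip_labels]
    elif hasattr(character, "loc"):
        obs = [str(x) for x in character.loc[list(tree.tip_labels)]]
    else:
        obs = [str(x) for x in character]
    from collections import Counter

    counts = Counter(obs)
    k = len(counts)
    if k < 2:
        raise ValueError("retention index undefined for an invariant character")
    m = k - 1
    g = len(obs) - max(counts.values())
    if g == m:
        raise ValueError("retention index undefined: g equals m")
    s = fitch_steps(tree, obs)
    return (g - s) / (g - m)
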