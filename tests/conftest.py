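"""Shared helpers: random tree construction and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from skullroof.phylogeny import Tree, parse_newick


def random_tree(n_tips: int, rng: np.random.Generator,
                prefix: str = "T") -> Tree:
    """Random binary tree by repeated pairwise joining (coalescent-style)."""
    nodes = [f"{prefix}{i}:{rng.uniform(0.2, 1.5):.4f}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[i], nodes[j]
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
        nodes.append(f"({a},{b}):{rng.uniform(0.2, 1.5):.4f}")
    core = nodes[0][: nodes[0].rfind(":")]
    return parse_newick(core + ";")


def shared_path_bruteforce(tree: Tree) -> np.ndarray:
    """Tip covariance by explicit root-to-tip edge-set intersection."""
    n = tree.n_tips
    paths = []
    for i in range(n):
        edges = {}
        u = i
        while tree.parent[u] >= 0:
            edges[u] = tree.blen[u]
            u = tree.parent[u]
        paths.append(edges)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            common = set(paths[i]) & set(paths[j])
            V[i, j] = sum(paths[i][e] for e in common)
    return V


def local_thickness_bruteforce(raster: np.ndarray) -> np.ndarray:
    """O(N^2) disc-coverage local thickness (same strict-coverage rule)."""
    from scipy import ndimage

    fg = np.asarray(raster).astype(bool)
    edt = ndimage.distance_transform_edt(fg)
    ys, xs = np.nonzero(fg)
    out = np.zeros(fg.shape)
    for cy, cx, r in zip(ys, xs, edt[ys, xs]):
        d2 = (ys - cy) ** 2 + (xs - cx) ** 2
        covered = d2 < r * r
        out[ys[covered], xs[covered]] = np.maximum(
            out[ys[covered], xs[covered]], 2.0 * r)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
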