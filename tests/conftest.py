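"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import evomorph as em
from evomorph.phylo import PhyloCovariance


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_tree():
    return em.Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def yule50():
    return em.simulate_tree(50, birth_rate=1.0, seed=7)


def star_cov(n: int, depth: float = 1.0) -> PhyloCovariance:
    """Star phylogeny covariance: C = depth · I."""
    return PhyloCovariance([f"s{i + 1}" for i in range(n)], depth * np.eye(n))


def pic_contrasts(tree: em.Phylogeny, values: dict[str, float]):
    """Felsenstein independent contrasts on a binary tree.

    Returns (standardized contrasts, root estimate). Independent of the GLS
    code path: pure pruning recursion.
    """
    dtree = tree.dendropy_tree
    contrasts = []

    node_val = {}
    node_len = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            node_val[node] = float(values[node.taxon.label])
            node_len[node] = float(node.edge.length or 0.0)
        else:
            kids = node.child_nodes()
            assert len(kids) == 2, "oracle requires a binary tree"
            x1, x2 = node_val[kids[0]], node_val[kids[1]]
            v1, v2 = node_len[kids[0]], node_len[kids[1]]
            contrasts.append((x1 - x2) / np.sqrt(v1 + v2))
            node_val[node] = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
            extra = v1 * v2 / (v1 + v2)
            node_len[node] = float(node.edge.length or 0.0) + extra
    root = dtree.seed_node
    return np.array(contrasts), node_val[root]


def naive_congruence(X: np.ndarray, k: int, d: int) -> np.ndarray:
    """Non-phylogenetic congruence oracle: centered per-coordinate dot products."""
    Xc = X - X.mean(axis=0)
    r = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            num = sum(Xc[:, i * d + c] @ Xc[:, j * d + c] for c in range(d))
            di = sum(Xc[:, i * d + c] @ Xc[:, i * d + c] for c in range(d))
            dj = sum(Xc[:, j * d + c] @ Xc[:, j * d + c] for c in range(d))
            r[i, j] = num / np.sqrt(di * dj)
    return r


def dense_bm_loglik(X: np.ndarray, C: np.ndarray, R: np.ndarray, root: np.ndarray) -> float:
    """Oracle: multivariate-normal log-density with the materialized Nk×Nk
    covariance kron(R, C), evaluated per dimension and summed."""
    from scipy.stats import multivariate_normal

    n, k, d = X.shape
    big = np.kron(R, C)
    total = 0.0
    for dim in range(d):
        # column-stacked vec: coordinate-major blocks of length n per landmark
        x = X[:, :, dim].T.ravel()
        mean = np.repeat(root[:, dim], n)
        total += multivariate_normal.logpdf(x, mean=mean, cov=big, allow_singular=False)
    return float(total)
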