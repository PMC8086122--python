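"""Phylogenetic linear algebra under Brownian motion.

The species×species matrix ``C`` of shared root-to-MRCA path lengths is the
covariance of tip values for a unit-rate Brownian trait. All generalized
least-squares (GLS) operations — the estimated root state E(X), phylogenetic
whitening, and the coordinate-level evolutionary rate matrix

    R = (X − E(X))' C⁻¹ (X − E(X)) / (N − 1)

— are computed through a cached Cholesky factor of C, never an explicit
inverse. When C is numerically indefinite its eigenvalues are clipped from
below (PSD repair) with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .datatypes import Phylogeny

__all__ = ["PhyloCovariance", "phylo_cov", "phylo_mean", "evol_rate_matrix"]


def _repaired_psd(C: np.ndarray, rel_floor: float = 1e-12) -> np.ndarray:
    vals, vecs = np.linalg.eigh(C)
    floor = rel_floor * vals.max()
    if vals.min() < floor:
        warnings.warn(
            "phylogenetic covariance is numerically singular; "
            f"clipping eigenvalues below {floor:.3g}",
            stacklevel=3,
        )
        vals = np.clip(vals, floor, None)
        C = (vecs * vals) @ vecs.T
        C = (C + C.T) / 2
    return C


@dataclass
class PhyloCovariance:
    """The N×N Brownian-motion tip covariance matrix with cached factorization."""

    species: list[str]
    matrix: np.ndarray
    _chol: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.species), len(self.species)):
            raise ValueError("matrix shape must match species list")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("phylogenetic covariance must be symmetric")

    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def chol(self) -> np.ndarray:
        """Lower Cholesky factor L with C = L Lᵀ (PSD-repaired if needed)."""
        if self._chol is None:
            try:
                self._chol = cholesky(self.matrix, lower=True)
            except (np.linalg.LinAlgError, ValueError):
                self.matrix = _repaired_psd(self.matrix)
                self._chol = cholesky(self.matrix, lower=True)
        return self._chol

    def solve(self, B: np.ndarray) -> np.ndarray:
        """C⁻¹ B via triangular solves."""
        L = self.chol
        y = solve_triangular(L, B, lower=True)
        return solve_triangular(L.T, y, lower=False)

    def whiten(self, X: np.ndarray) -> np.ndarray:
        """L⁻¹ X, the phylogenetic transform: rows become iid under BM."""
        return solve_triangular(self.chol, X, lower=True)

    def logdet(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self.chol))))

    def subset(self, species: list[str]) -> "PhyloCovariance":
        index = {s: i for i, s in enumerate(self.species)}
        rows = np.array([index[s] for s in species])
        return PhyloCovariance(list(species), self.matrix[np.ix_(rows, rows)])


def phylo_cov(tree: Phylogeny) -> PhyloCovariance:
    """Shared-path-length matrix: C[i, j] = root→MRCA(i, j) path length.

    Diagonal entries are tip depths. Polytomies are handled naturally.
    """
    dtree = tree.dendropy_tree
    if dtree.seed_node is None:
        raise ValueError("tree is not rooted")
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    depths: dict = {}
    for node in dtree.preorder_node_iter():
        parent = node.parent_node
        depths[node] = 0.0 if parent is None else depths[parent] + node.edge.length

    tipsets: dict = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            C[i, i] = depths[node]
            tipsets[node] = np.array([i])
        else:
            children = [tipsets.pop(ch) for ch in node.child_nodes()]
            depth = depths[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    C[np.ix_(children[a], children[b])] = depth
                    C[np.ix_(children[b], children[a])] = depth
            tipsets[node] = np.concatenate(children)
    return PhyloCovariance(labels, C)


def phylo_mean(X: np.ndarray, C: PhyloCovariance) -> np.ndarray:
    """GLS estimate of the Brownian root state, per column of X.

    a = (1ᵗ C⁻¹ 1)⁻¹ 1ᵗ C⁻¹ X. With C = I this is the column mean.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != C.n:
        raise ValueError("X rows must match species count")
    ones = np.ones((C.n, 1))
    Cinv1 = C.solve(ones)
    return (Cinv1.T @ X).ravel() / float((ones.T @ Cinv1)[0, 0])


def evol_rate_matrix(
    X: np.ndarray,
    C: PhyloCovariance,
    divisor: str = "n_minus_1",
) -> np.ndarray:
    """Coordinate-level evolutionary rate/covariance matrix.

    R = (X − E(X))ᵗ C⁻¹ (X − E(X)) / divisor, where E(X) is the GLS root
    state broadcast over species. ``divisor`` is ``"n_minus_1"`` or ``"n"``.
    With C = I and divisor N−1 this is the ordinary sample covariance about
    the mean. Result is symmetric p×p.
    """
    X = np.asarray(X, dtype=float)
    n = C.n
    if X.shape[0] != n:
        raise ValueError("X rows must match species count")
    if n < 3:
        raise ValueError("need at least 3 species")
    if divisor not in ("n_minus_1", "n"):
        raise ValueError(f"unknown divisor {divisor!r}")
    a = phylo_mean(X, C)
    Xc = X - a[None, :]
    W = C.whiten(Xc)
    R = W.T @ W
    R /= (n - 1) if divisor == "n_minus_1" else n
    return (R + R.T) / 2
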