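"""Phylogenetically corrected landmark congruence and module detection.

From the coordinate-level evolutionary rate matrix R (landmark-major order),
the congruence coefficient between landmarks L1 and L2 is

    r = trace(R_{L1,L2}) / sqrt(trace(R_{L1,L1}) · trace(R_{L2,L2}))

where each block is the d×d sub-matrix of R for one landmark pair. The
number of modules is chosen by comparing eigenvalue proportions of the
congruence matrix against the broken-stick null, and landmark-to-module
assignment uses Ward agglomeration on a convex mix of the congruence-derived
dissimilarity D0 and a geometric constraint D1 (inter-landmark distances in
the consensus configuration), each rescaled by its maximum so the mixing
weight α is comparable across datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ModuleHypothesis

__all__ = [
    "CongruenceMatrix",
    "ModuleDetection",
    "congruence_matrix",
    "broken_stick_modules",
    "constrained_ward",
    "choice_alpha",
    "detect_modules",
]


@dataclass
class CongruenceMatrix:
    """Symmetric k×k matrix of landmark congruence coefficients, unit diagonal.

    Landmarks with zero variance get NaN rows/columns and are excluded from
    clustering.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("values shape must match labels")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.max(np.abs(finite)) > 1 + 1e-9:
            raise ValueError("congruence coefficients must lie in [-1, 1]")

    @property
    def k(self) -> int:
        return len(self.labels)

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(np.diag(self.values))

    def eigenvalues(self) -> np.ndarray:
        """Descending eigenvalues over the valid landmarks."""
        mask = self.valid_mask()
        vals = np.linalg.eigvalsh(self.values[np.ix_(mask, mask)])
        return vals[::-1]


@dataclass
class ModuleDetection:
    n_modules: int
    hypothesis: ModuleHypothesis
    merges: np.ndarray  # (k−1) × 4 linkage-style table (id1, id2, height, size)
    eigenvalues: np.ndarray
    broken_stick: np.ndarray
    alpha: float


def congruence_matrix(R: np.ndarray, d: int, labels: list[str] | None = None) -> CongruenceMatrix:
    """Congruence coefficients from the p×p rate matrix (p = k·d, landmark-major)."""
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p) or p % d != 0:
        raise ValueError("R must be square with size divisible by d")
    k = p // d
    R4 = R.reshape(k, d, k, d)
    tr = np.einsum("adbd->ab", R4)
    diag = np.diag(tr).copy()
    bad = diag <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} landmark(s) with zero variance trace; "
            "their congruence rows are undefined (NaN)",
            stacklevel=2,
        )
    denom = np.sqrt(np.outer(np.where(bad, np.nan, diag), np.where(bad, np.nan, diag)))
    with np.errstate(invalid="ignore"):
        r = tr / denom
    r = np.clip(r, -1.0, 1.0, out=r, where=np.isfinite(r))
    np.fill_diagonal(r, 1.0)
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    r = np.where(np.isfinite(r) & np.isfinite(r.T), (r + r.T) / 2, r)
    if labels is None:
        labels = [f"L{i + 1}" for i in range(k)]
    return CongruenceMatrix(labels, r)


def broken_stick_modules(evals: np.ndarray) -> int:
    """Count of leading eigenvalues whose proportion exceeds broken-stick expectation.

    The count stops at the first failure (contiguous leading run). If no
    eigenvalue exceeds its expectation, 1 is returned (no modularity) with a
    warning.
    """
    evals = np.asarray(evals, dtype=float)
    if np.any(np.diff(evals) > 1e-9):
        raise ValueError("eigenvalues must be in descending order")
    k = evals.size
    total = evals.sum()
    props = evals / total
    # b_i = (1/k) Σ_{j=i..k} 1/j
    inv = 1.0 / np.arange(1, k + 1)
    b = np.cumsum(inv[::-1])[::-1] / k
    m = 0
    for i in range(k):
        if props[i] > b[i]:
            m += 1
        else:
            break
    if m == 0:
        warnings.warn("no eigenvalue exceeds broken-stick expectation; reporting m = 1")
        return 1
    return m


def _corr_to_dist(r: np.ndarray) -> np.ndarray:
    """d = sqrt(2(1 − r)): the Euclidean embedding distance for correlations."""
    return np.sqrt(np.maximum(2.0 * (1.0 - r), 0.0))


def _ward_merges(d2: np.ndarray) -> np.ndarray:
    """Lance–Williams Ward agglomeration on a squared-dissimilarity matrix.

    Returns a linkage-style (n−1)×4 table: merged cluster ids (originals
    0..n−1, new clusters n, n+1, ...), the merge cost ΔI, and the new cluster
    size. Ties are broken deterministically by the lowest original landmark
    index pair of the candidate clusters.
    """
    n = d2.shape[0]
    D = d2.astype(float).copy()
    sizes = {i: 1 for i in range(n)}
    min_idx = {i: i for i in range(n)}  # lowest original index in cluster
    ids = {i: i for i in range(n)}  # row → current cluster id
    active = list(range(n))
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            i = active[ai]
            for bi in range(ai + 1, len(active)):
                j = active[bi]
                ni, nj = sizes[i], sizes[j]
                cost = ni * nj / (ni + nj) * D[i, j]
                lo, hi = sorted((min_idx[i], min_idx[j]))
                key = (cost, lo, hi)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (cost, _, _), i, j = best
        ni, nj = sizes[i], sizes[j]
        # Lance–Williams update of squared center distances, stored in row i
        for kk in active:
            if kk in (i, j):
                continue
            nk = sizes[kk]
            D[i, kk] = D[kk, i] = (
                (ni + nk) * D[kk, i] + (nj + nk) * D[kk, j] - nk * D[i, j]
            ) / (ni + nj + nk)
        merges[step] = (ids[i], ids[j], cost, ni + nj)
        sizes[i] = ni + nj
        min_idx[i] = min(min_idx[i], min_idx[j])
        ids[i] = next_id
        next_id += 1
        active.remove(j)
    return merges


def _cut_merges(merges: np.ndarray, n: int, m: int) -> np.ndarray:
    """Labels 1..m from the first n−m merges, renumbered by first occurrence."""
    parent = list(range(n + merges.shape[0]))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - m):
        a, b = int(merges[step, 0]), int(merges[step, 1])
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new
    roots = [find(i) for i in range(n)]
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    return labels


def _mixed_d2(D0: np.ndarray, D1: np.ndarray, alpha: float) -> np.ndarray:
    s0 = D0.max() or 1.0
    s1 = D1.max() or 1.0
    return (1.0 - alpha) * (D0 / s0) ** 2 + alpha * (D1 / s1) ** 2


def constrained_ward(
    cm: CongruenceMatrix,
    coords: np.ndarray,
    m: int,
    alpha: float = 0.5,
    fold_abs: bool = False,
) -> ModuleDetection:
    """Geometrically constrained Ward clustering of landmarks into m modules.

    At each agglomeration step the merge minimizes the mixed Ward criterion
    (1−α)·ΔI(D0) + α·ΔI(D1), where D0 = √(2(1−r)) from the congruence matrix
    (optionally folded to |r|) and D1 is the matrix of inter-landmark
    Euclidean distances in the consensus configuration; each matrix is
    rescaled by its maximum before mixing. α = 0 is plain Ward on the
    congruence dissimilarity, α = 1 plain Ward on geometry alone.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    mask = cm.valid_mask()
    kv = int(mask.sum())
    if m < 1 or m > kv:
        raise ValueError(f"m must lie in [1, {kv}]")
    r = cm.values[np.ix_(mask, mask)]
    if fold_abs:
        r = np.abs(r)
    D0 = _corr_to_dist(r)
    coords = np.asarray(coords, dtype=float)[mask]
    diff = coords[:, None, :] - coords[None, :, :]
    D1 = np.sqrt((diff**2).sum(axis=-1))
    d2 = _mixed_d2(D0, D1, alpha)
    merges = _ward_merges(d2)
    labels_valid = _cut_merges(merges, kv, m)
    assignment = np.empty(cm.k, dtype=int)
    assignment[mask] = labels_valid
    if (~mask).any():
        # undefined landmarks are appended to their own trailing module
        assignment[~mask] = labels_valid.max() + 1
    evals = cm.eigenvalues()
    inv = 1.0 / np.arange(1, evals.size + 1)
    bstick = np.cumsum(inv[::-1])[::-1] / evals.size
    hyp = ModuleHypothesis(name=f"detected_m{m}_a{alpha:g}", assignment=assignment)
    return ModuleDetection(
        n_modules=int(assignment.max()),
        hypothesis=hyp,
        merges=merges,
        eigenvalues=evals,
        broken_stick=bstick,
        alpha=alpha,
    )


def _pseudo_inertia(d2: np.ndarray, members: np.ndarray) -> float:
    """Σ_{i<j∈cluster} d²_ij / n_cluster (uniform weights)."""
    sub = d2[np.ix_(members, members)]
    return float(np.triu(sub, 1).sum() / members.size)


def choice_alpha(
    D0: np.ndarray,
    D1: np.ndarray,
    alphas,
    m: int,
) -> pd.DataFrame:
    """Explained-inertia curves across the α grid, for the operator to choose α.

    For each α, cluster on the mixed criterion and report the proportion of
    each (max-normalized) matrix's total pseudo-inertia explained by the
    m-cluster partition.
    """
    D0 = np.asarray(D0, float) / (np.asarray(D0, float).max() or 1.0)
    D1 = np.asarray(D1, float) / (np.asarray(D1, float).max() or 1.0)
    n = D0.shape[0]
    rows = []
    all_idx = np.arange(n)
    T0 = _pseudo_inertia(D0**2, all_idx)
    T1 = _pseudo_inertia(D1**2, all_idx)
    for alpha in alphas:
        d2 = (1 - alpha) * D0**2 + alpha * D1**2
        labels = _cut_merges(_ward_merges(d2), n, m)
        W0 = sum(_pseudo_inertia(D0**2, np.flatnonzero(labels == g)) for g in np.unique(labels))
        W1 = sum(_pseudo_inertia(D1**2, np.flatnonzero(labels == g)) for g in np.unique(labels))
        rows.append(
            {
                "alpha": float(alpha),
                "explained_D0": 1.0 - W0 / T0 if T0 > 0 else 1.0,
                "explained_D1": 1.0 - W1 / T1 if T1 > 0 else 1.0,
            }
        )
    return pd.DataFrame(rows)


def detect_modules(
    cm: CongruenceMatrix,
    coords: np.ndarray,
    m: int | None = None,
    alpha: float = 0.5,
    fold_abs: bool = False,
) -> ModuleDetection:
    """Full detection: broken-stick module count (unless given), then clustering."""
    if m is None:
        m = broken_stick_modules(cm.eigenvalues())
    return constrained_ward(cm, coords, m=m, alpha=alpha, fold_abs=fold_abs)
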